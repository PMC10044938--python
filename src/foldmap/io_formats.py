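"""Readers and writers for the standard RNA structure text formats.

Supported formats:

* FASTA — sequences only (via Bio.SeqIO).
* CT — 6-column connectivity table: index, base, previous, next, pair, index.
  Header line is ``L  id`` (energy annotations after the length are
  tolerated on read).
* BPSEQ — 3-column dialect: index, base, pair (0 = unpaired).
* dot-bracket — nested pairs as ``()``; crossing pairs are assigned extra
  bracket tiers ``[] {} <>`` by greedy coloring of the crossing graph.

File coordinates are 1-based throughout, as the formats require; everything
in memory is 0-based except the ``pairs`` field of :class:`StructureRecord`,
which keeps the 1-based convention of the files it round-trips with.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Set, Tuple

from Bio import SeqIO

from .sequence import RnaSequence, make_sequence

BRACKET_TIERS = [("(", ")"), ("[", "]"), ("{", "}"), ("<", ">")]


class StructureFormatError(ValueError):
    """Raised on malformed or inconsistent structure files."""


@dataclass(frozen=True)
class StructureRecord:
    """A sequence together with its set of base pairs (1-based, i < j)."""

    id: str
    sequence: RnaSequence
    pairs: frozenset  # of (i, j) tuples, 1-based, i < j

    def __post_init__(self) -> None:
        L = len(self.sequence)
        seen: Set[int] = set()
        for i, j in self.pairs:
            if not (1 <= i < j <= L):
                raise StructureFormatError(
                    f"record {self.id!r}: pair ({i}, {j}) out of range for L={L}"
                )
            if i in seen or j in seen:
                raise StructureFormatError(
                    f"record {self.id!r}: base in more than one pair"
                )
            seen.update((i, j))

    @property
    def length(self) -> int:
        return len(self.sequence)

    def partner_array(self) -> List[int]:
        """partner[i] (1-based list of length L+1; 0 = unpaired)."""
        partner = [0] * (self.length + 1)
        for i, j in self.pairs:
            partner[i], partner[j] = j, i
        return partner


def make_record(id: str, bases: str, pairs) -> StructureRecord:
    return StructureRecord(
        id=id, sequence=make_sequence(bases, id=id), pairs=frozenset(pairs)
    )


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path, strict: bool = True) -> List[RnaSequence]:
    """Read a multi-record FASTA into validated RNA sequences.

    Uppercases; with ``strict=False`` maps T->U first (DNA-style input).
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise StructureFormatError(f"no FASTA records found in {path}")
    out = []
    for rec in records:
        try:
            out.append(make_sequence(str(rec.seq), id=rec.id, strict=strict))
        except ValueError as exc:
            raise StructureFormatError(f"record {rec.id!r}: {exc}") from exc
    return out


def write_fasta(seqs, path) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id or 'seq'}\n{s.bases}\n")


# ---------------------------------------------------------------------------
# CT

def write_ct(record: StructureRecord, path) -> None:
    partner = record.partner_array()
    L = record.length
    with open(path, "w") as fh:
        fh.write(f"{L}\t{record.id}\n")
        for i in range(1, L + 1):
            fh.write(
                f"{i}\t{record.sequence.bases[i - 1]}\t{i - 1}\t"
                f"{(i + 1) % (L + 1)}\t{partner[i]}\t{i}\n"
            )


def read_ct(path) -> StructureRecord:
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise StructureFormatError(f"empty CT file {path}")
    header = lines[0].split()
    try:
        L = int(header[0])
    except (ValueError, IndexError) as exc:
        raise StructureFormatError(f"{path}: malformed CT header {lines[0]!r}") from exc
    rec_id = header[1] if len(header) > 1 and not header[1].startswith(("ENERGY", "dG")) \
        else (header[-1] if len(header) > 1 else path.stem)
    body = lines[1 : 1 + L]
    if len(body) != L:
        raise StructureFormatError(f"{path}: expected {L} body lines, got {len(body)}")
    bases, partner = [], [0] * (L + 1)
    for expected, ln in enumerate(body, start=1):
        cols = ln.split()
        if len(cols) < 5:
            raise StructureFormatError(f"{path}: short CT line {ln!r}")
        idx = int(cols[0])
        if idx != expected:
            raise StructureFormatError(f"{path}: index gap at line {expected}")
        bases.append(cols[1])
        partner[idx] = int(cols[4])
    _check_partner_symmetry(partner, path)
    pairs = {(i, partner[i]) for i in range(1, L + 1) if partner[i] > i}
    return make_record(rec_id, "".join(bases), pairs)


# ---------------------------------------------------------------------------
# BPSEQ

def write_bpseq(record: StructureRecord, path) -> None:
    partner = record.partner_array()
    with open(path, "w") as fh:
        for i in range(1, record.length + 1):
            fh.write(f"{i} {record.sequence.bases[i - 1]} {partner[i]}\n")


def read_bpseq(path, rec_id: str | None = None) -> StructureRecord:
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise StructureFormatError(f"empty BPSEQ file {path}")
    bases, partner = [], [0]
    for expected, ln in enumerate(lines, start=1):
        cols = ln.split()
        if len(cols) != 3:
            raise StructureFormatError(f"{path}: malformed BPSEQ line {ln!r}")
        idx = int(cols[0])
        if idx != expected:
            raise StructureFormatError(f"{path}: index gap at line {expected}")
        bases.append(cols[1])
        partner.append(int(cols[2]))
    _check_partner_symmetry(partner, path)
    L = len(bases)
    pairs = {(i, partner[i]) for i in range(1, L + 1) if partner[i] > i}
    return make_record(rec_id or path.stem, "".join(bases), pairs)


def _check_partner_symmetry(partner: List[int], path) -> None:
    L = len(partner) - 1
    for i in range(1, L + 1):
        j = partner[i]
        if j:
            if not 1 <= j <= L or j == i:
                raise StructureFormatError(f"{path}: pair index {j} out of range")
            if partner[j] != i:
                raise StructureFormatError(
                    f"{path}: asymmetric pairing {i}->{j} but {j}->{partner[j]}"
                )


# ---------------------------------------------------------------------------
# dot-bracket

def pairs_to_dotbracket(pairs, L: int) -> str:
    """Dot-bracket string; crossing pairs get higher bracket tiers.

    Pairs (1-based, i < j) are processed in ascending i and assigned the
    lowest tier whose already-assigned pairs they do not cross. Emits a
    warning and reuses the last tier if more than four are needed.
    """
    sorted_pairs = sorted(pairs)
    tiers: List[List[Tuple[int, int]]] = [[] for _ in BRACKET_TIERS]
    assignment: Dict[Tuple[int, int], int] = {}
    for i, j in sorted_pairs:
        placed = False
        for t, members in enumerate(tiers):
            if all(not _crosses((i, j), m) for m in members):
                members.append((i, j))
                assignment[(i, j)] = t
                placed = True
                break
        if not placed:
            warnings.warn(
                f"more than {len(BRACKET_TIERS)} bracket tiers needed; "
                "dot-bracket output is lossy", stacklevel=2,
            )
            tiers[-1].append((i, j))
            assignment[(i, j)] = len(BRACKET_TIERS) - 1
    chars = ["."] * L
    for (i, j), t in assignment.items():
        chars[i - 1], chars[j - 1] = BRACKET_TIERS[t]
    return "".join(chars)


def _crosses(a: Tuple[int, int], b: Tuple[int, int]) -> bool:
    (i1, j1), (i2, j2) = sorted((a, b))
    return i1 < i2 < j1 < j2


def parse_dotbracket(structure: str) -> Set[Tuple[int, int]]:
    """Pairs (1-based) from a dot-bracket string with up to four tiers."""
    stacks: Dict[str, List[int]] = {op: [] for op, _ in BRACKET_TIERS}
    closers = {cl: op for op, cl in BRACKET_TIERS}
    pairs: Set[Tuple[int, int]] = set()
    for pos, ch in enumerate(structure, start=1):
        if ch in stacks:
            stacks[ch].append(pos)
        elif ch in closers:
            stack = stacks[closers[ch]]
            if not stack:
                raise StructureFormatError(f"unbalanced bracket at position {pos}")
            pairs.add((stack.pop(), pos))
        elif ch not in ".-_,:":
            raise StructureFormatError(f"unexpected character {ch!r} at position {pos}")
    for op, stack in stacks.items():
        if stack:
            raise StructureFormatError(f"unclosed {op!r} bracket")
    return pairs


def write_dotbracket(record: StructureRecord, path) -> None:
    """Write a 3-line dbn file: header, sequence, structure."""
    with open(path, "w") as fh:
        fh.write(f">{record.id}\n{record.sequence.bases}\n")
        fh.write(pairs_to_dotbracket(record.pairs, record.length) + "\n")
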