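"""Synthetic RNA sequence + structure corpora.

The generator works structure-first: it places stems (runs of nested base
pairs) with hairpin loops of at least 3 unpaired bases, so every emitted
pair satisfies the decoder's |i - j| >= 4 separation rule by construction,
then samples a compatible sequence (canonical A-U/C-G pairs plus G-U wobble
at a configurable frequency, unpaired positions uniform).

With probability ``pseudoknot_probability`` a structure receives one H-type
pseudoknot: two stems whose pairs cross (i1 < i2 < j1 < j2), the minimal
topology that exercises non-nested decoding. These corpora exercise code
paths; they make no claim to thermodynamic realism or to the length/family
statistics of curated databases.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import List, Set, Tuple

import numpy as np

from .io_formats import StructureRecord, make_record, write_ct, write_fasta
from .sequence import BASES

Pair = Tuple[int, int]  # 0-based, i < j


@dataclass
class FixtureConfig:
    """Knobs of the synthetic corpus.

    Lengths are in bases; ``stem_min``/``stem_max`` bound the number of
    stacked pairs per stem; ``gu_fraction`` is the probability that a paired
    position becomes a G-U wobble rather than a Watson-Crick pair.
    """

    n_sequences: int = 40
    length_min: int = 30
    length_max: int = 70
    stem_min: int = 3
    stem_max: int = 6
    pseudoknot_probability: float = 0.3
    gu_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.pseudoknot_probability <= 1.0:
            raise ValueError("pseudoknot_probability must be in [0, 1]")
        if not 0.0 <= self.gu_fraction <= 1.0:
            raise ValueError("gu_fraction must be in [0, 1]")
        if self.pseudoknot_probability > 0 and self.length_min < 20:
            raise ValueError(
                "length_min must be >= 20 when pseudoknots are enabled "
                "(two crossing stems need room under the separation rule)"
            )
        if self.stem_min < 1 or self.stem_max < self.stem_min:
            raise ValueError("invalid stem length range")
        if self.length_min < 12 or self.length_max < self.length_min:
            raise ValueError("invalid length range")


def has_crossing(pairs) -> bool:
    """True if any two pairs cross (i1 < i2 < j1 < j2)."""
    ps = sorted(pairs)
    for a in range(len(ps)):
        i1, j1 = ps[a]
        for b in range(a + 1, len(ps)):
            i2, j2 = ps[b]
            if i1 < i2 < j1 < j2:
                return True
    return False


def _fill_nested(lo: int, hi: int, cfg: FixtureConfig, rng, pairs: Set[Pair],
                 force: bool = False) -> None:
    """Place a stem inside the free interval [lo, hi] and recurse inward."""
    if hi - lo + 1 < 2 * cfg.stem_min + 3:
        return
    if not force and rng.random() < 0.25:  # leave some regions unpaired
        return
    max_s = (hi - lo + 1 - 3) // 2
    s = int(rng.integers(cfg.stem_min, min(cfg.stem_max, max_s) + 1))
    slack = (hi - lo + 1) - (2 * s + 3)
    off_l = int(rng.integers(0, slack + 1))
    off_r = int(rng.integers(0, slack - off_l + 1))
    a, b = lo + off_l, hi - off_r
    for k in range(s):
        pairs.add((a + k, b - k))
    _fill_nested(a + s, b - s, cfg, rng, pairs)


def _place_pseudoknot(L: int, cfg: FixtureConfig, rng, pairs: Set[Pair]) -> None:
    """One H-type pseudoknot: stems A-C and B-D over segments A < B < C < D."""
    for _ in range(50):  # rejection-sample a feasible layout
        s1 = int(rng.integers(cfg.stem_min, cfg.stem_max + 1))
        s2 = int(rng.integers(cfg.stem_min, cfg.stem_max + 1))
        need = 2 * s1 + 2 * s2 + 6  # two loops of >= 3
        if need > L:
            continue
        a = int(rng.integers(0, L - need + 1))
        b = a + s1 + int(rng.integers(0, max(1, (L - need) // 4)))
        c = max(b + s2, a + s1 + 3)
        c += int(rng.integers(0, 2))
        d = max(c + s1, b + s2 + 3)
        if d + s2 > L:
            continue
        for k in range(s1):
            pairs.add((a + k, c + s1 - 1 - k))
        for k in range(s2):
            pairs.add((b + k, d + s2 - 1 - k))
        return
    raise ValueError(f"could not place a pseudoknot in length {L}")


def sample_structure(L: int, cfg: FixtureConfig, rng) -> Set[Pair]:
    """Sample a feasible pair set (0-based) for a sequence of length L."""
    if not cfg.length_min <= L <= cfg.length_max:
        raise ValueError(f"L={L} outside configured bounds")
    pairs: Set[Pair] = set()
    if rng.random() < cfg.pseudoknot_probability:
        _place_pseudoknot(L, cfg, rng, pairs)
        tail = max((j for _, j in pairs)) + 1
        _fill_nested(tail + 1, L - 1, cfg, rng, pairs)
    else:
        _fill_nested(0, L - 1, cfg, rng, pairs, force=True)
        # occasionally a second top-level stem after the first one
        if pairs:
            tail = max(j for _, j in pairs) + 1
            _fill_nested(tail + 1, L - 1, cfg, rng, pairs)
    return pairs


_WC = ["AU", "UA", "CG", "GC"]
_WOBBLE = ["GU", "UG"]


def sample_sequence(pairs: Set[Pair], L: int, cfg: FixtureConfig, rng) -> str:
    """Sample bases consistent with the pair set."""
    seq = [BASES[int(k)] for k in rng.integers(0, 4, size=L)]
    for i, j in pairs:
        if rng.random() < cfg.gu_fraction:
            duo = _WOBBLE[int(rng.integers(0, 2))]
        else:
            duo = _WC[int(rng.integers(0, 4))]
        seq[i], seq[j] = duo[0], duo[1]
    return "".join(seq)


def generate_corpus(cfg: FixtureConfig) -> List[StructureRecord]:
    """Generate ``cfg.n_sequences`` records, deterministically from the seed."""
    rng = np.random.default_rng(cfg.seed)
    records = []
    for n in range(cfg.n_sequences):
        L = int(rng.integers(cfg.length_min, cfg.length_max + 1))
        pairs0 = sample_structure(L, cfg, rng)
        bases = sample_sequence(pairs0, L, cfg, rng)
        records.append(
            make_record(
                f"synth{n:04d}", bases, {(i + 1, j + 1) for i, j in pairs0}
            )
        )
    return records


def emit_corpus(cfg: FixtureConfig, out_dir) -> List[StructureRecord]:
    """Write a corpus to disk: one FASTA, per-record CT files, manifest TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = generate_corpus(cfg)
    write_fasta([r.sequence for r in records], out / "corpus.fasta")
    with open(out / "manifest.tsv", "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["id", "length", "n_pairs", "pseudoknot", "ct_file"])
        for r in records:
            ct_name = f"{r.id}.ct"
            write_ct(r, out / ct_name)
            pk = has_crossing({(i - 1, j - 1) for i, j in r.pairs})
            w.writerow([r.id, r.length, len(r.pairs), int(pk), ct_name])
    return records
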