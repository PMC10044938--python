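"""Contact-matrix encoding of an RNA sequence.

A length-L sequence is turned into a stack of 146 binary L x L contact
matrices ("the input conformation"):

* 10 dinucleotide channels — one per unordered base pair {x, y} with
  x, y in {A, C, G, U}. Channel c has a 1 at (i, j) iff {b_i, b_j} is the
  c-th unordered pair. Order-insensitivity makes the encoding robust to
  strand-symmetric mutations (an AU contact and a UA contact light the same
  channel).
* 136 tetranucleotide channels — one per unordered pair of dimers (2-mers),
  16 * 17 / 2 = 136 classes. Channel c has a 1 at (i, j) iff the unordered
  pair {b_i b_{i+1}, b_j b_{j+1}} is the c-th dimer pair. The dimer at the
  last position wraps around to (b_{L-1}, b_0), so the terminal row/column
  carries signal for circular RNAs instead of being undefined.

For any cell (i, j) exactly one dinucleotide channel and exactly one
tetranucleotide channel are set, every channel slice is symmetric, and the
full tensor has shape (146, L, L).

Channel order is frozen (lexicographic over sorted pair members; bases
A < C < G < U, dimers in 16-way lexicographic order) so that saved model
weights remain meaningful across runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations_with_replacement, product
from typing import Tuple

import numpy as np

from .sequence import BASES, RnaSequence

N_DINUCLEOTIDE_CHANNELS = 10
N_TETRANUCLEOTIDE_CHANNELS = 136
N_CHANNELS = N_DINUCLEOTIDE_CHANNELS + N_TETRANUCLEOTIDE_CHANNELS

#: The 10 unordered base pairs, lexicographic over the sorted pair.
DINUCLEOTIDE_CLASSES: Tuple[str, ...] = tuple(
    a + b for a, b in combinations_with_replacement(BASES, 2)
)

#: The 16 dimers in lexicographic order.
DIMERS: Tuple[str, ...] = tuple(a + b for a, b in product(BASES, repeat=2))

#: The 136 unordered dimer pairs, lexicographic over the sorted pair.
TETRANUCLEOTIDE_CLASSES: Tuple[str, ...] = tuple(
    x + y for x, y in combinations_with_replacement(DIMERS, 2)
)

# 4x4 lookup: (base index, base index) -> dinucleotide class id.
_PAIR_CLASS = np.empty((4, 4), dtype=np.int64)
for _c, (_a, _b) in enumerate(combinations_with_replacement(range(4), 2)):
    _PAIR_CLASS[_a, _b] = _c
    _PAIR_CLASS[_b, _a] = _c

# 16x16 lookup: (dimer index, dimer index) -> tetranucleotide class id.
_DIMER_PAIR_CLASS = np.empty((16, 16), dtype=np.int64)
for _c, (_x, _y) in enumerate(combinations_with_replacement(range(16), 2)):
    _DIMER_PAIR_CLASS[_x, _y] = _c
    _DIMER_PAIR_CLASS[_y, _x] = _c

#: Channel names, dinucleotide channels first.
CHANNEL_NAMES: Tuple[str, ...] = DINUCLEOTIDE_CLASSES + tuple(
    f"{x}-{y}" for x, y in (
        (c[:2], c[2:]) for c in TETRANUCLEOTIDE_CLASSES
    )
)


@dataclass(frozen=True)
class InputConformation:
    """The 146 x L x L binary contact-matrix stack for one sequence."""

    tensor: np.ndarray  # (146, L, L) uint8
    sequence: RnaSequence

    @property
    def length(self) -> int:
        return self.tensor.shape[-1]

    def __post_init__(self) -> None:
        if self.tensor.shape != (N_CHANNELS, len(self.sequence), len(self.sequence)):
            raise ValueError(
                f"conformation tensor has shape {self.tensor.shape}, expected "
                f"({N_CHANNELS}, {len(self.sequence)}, {len(self.sequence)})"
            )


def pair_class_of(a: str, b: str) -> int:
    """Class id in [0, 10) of the unordered base pair {a, b}.

    Symmetric by construction: ``pair_class_of(a, b) == pair_class_of(b, a)``.
    """
    try:
        return int(_PAIR_CLASS[BASES.index(a), BASES.index(b)])
    except ValueError as exc:
        raise ValueError(f"invalid base in pair ({a!r}, {b!r})") from exc


def dimer_at(seq: RnaSequence, i: int) -> str:
    """The ordered dimer starting at 0-based position i.

    For ``i < L-1`` this is ``(b_i, b_{i+1})``; the final position wraps to
    ``(b_{L-1}, b_0)``, treating the chain as circular at the terminus.
    """
    L = len(seq)
    if not 0 <= i < L:
        raise IndexError(f"dimer index {i} out of range for length {L}")
    if i == L - 1:
        return seq.bases[L - 1] + seq.bases[0]
    return seq.bases[i : i + 2]


def _dimer_indices(seq: RnaSequence) -> np.ndarray:
    b = seq.indices()
    nxt = np.roll(b, -1)  # position L-1 wraps to b_0
    return 4 * b + nxt


def encode_dinucleotide(seq: RnaSequence) -> np.ndarray:
    """10 x L x L binary tensor of unordered base-pair occupancy."""
    b = seq.indices()
    classes = _PAIR_CLASS[b[:, None], b[None, :]]  # (L, L)
    out = np.zeros((N_DINUCLEOTIDE_CHANNELS, len(seq), len(seq)), dtype=np.uint8)
    ii, jj = np.indices(classes.shape)
    out[classes, ii, jj] = 1
    return out


def encode_tetranucleotide(seq: RnaSequence) -> np.ndarray:
    """136 x L x L binary tensor of unordered dimer-pair occupancy."""
    d = _dimer_indices(seq)
    classes = _DIMER_PAIR_CLASS[d[:, None], d[None, :]]  # (L, L)
    out = np.zeros((N_TETRANUCLEOTIDE_CHANNELS, len(seq), len(seq)), dtype=np.uint8)
    ii, jj = np.indices(classes.shape)
    out[classes, ii, jj] = 1
    return out


def build_input_conformation(seq: RnaSequence) -> InputConformation:
    """Assemble the full 146 x L x L input conformation.

    Channels 0-9 are the dinucleotide matrices, channels 10-145 the
    tetranucleotide matrices, in the frozen lexicographic order of
    :data:`CHANNEL_NAMES`.
    """
    tensor = np.concatenate(
        [encode_dinucleotide(seq), encode_tetranucleotide(seq)], axis=0
    )
    return InputConformation(tensor=tensor, sequence=seq)


def export_channels(conf: InputConformation, path: str) -> None:
    """Dump the conformation as an NPZ keyed by channel name (debug aid)."""
    np.savez_compressed(
        path, **{name: conf.tensor[c] for c, name in enumerate(CHANNEL_NAMES)}
    )
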