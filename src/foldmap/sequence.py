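"""RNA sequence container and validation.

The alphabet is the four ribonucleotides A, C, G, U. Strict mode rejects any
other character, mirroring the common practice of excluding sequences with
unknown bases from structure benchmarks. Lenient mode maps T to U (DNA-style
input) and replaces other IUPAC ambiguity codes with ``N`` placeholders that
downstream encoders treat as zero channels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

BASES = "ACGU"
_BASE_TO_INDEX = {b: i for i, b in enumerate(BASES)}


class InvalidBaseError(ValueError):
    """Raised when a sequence contains characters outside {A, C, G, U}."""


@dataclass(frozen=True)
class RnaSequence:
    """A validated RNA sequence.

    Parameters
    ----------
    bases:
        Uppercase string over ``{A, C, G, U}``.
    id:
        Free-text identifier (e.g. the FASTA header).
    """

    bases: str
    id: str = ""

    def __post_init__(self) -> None:
        if len(self.bases) < 1:
            raise ValueError("RNA sequence must have length >= 1")
        bad = set(self.bases) - set(BASES)
        if bad:
            raise InvalidBaseError(
                f"sequence {self.id!r} contains non-ACGU characters: {sorted(bad)}"
            )
        if len(self.bases) == 1:
            warnings.warn(
                f"sequence {self.id!r} has length 1; encodings are degenerate",
                stacklevel=2,
            )

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def length(self) -> int:
        return len(self.bases)

    def indices(self):
        """Base identities as integers A=0, C=1, G=2, U=3 (numpy array)."""
        import numpy as np

        return np.array([_BASE_TO_INDEX[b] for b in self.bases], dtype=np.int64)


def make_sequence(raw: str, id: str = "", strict: bool = True) -> RnaSequence:
    """Normalize and validate a raw string into an :class:`RnaSequence`.

    Strict mode raises :class:`InvalidBaseError` on anything outside ACGU
    (after uppercasing). Lenient mode additionally maps T->U; remaining
    unknown codes still raise, because the encoders have no channel for them.
    """
    s = raw.strip().upper().replace(" ", "")
    if not strict:
        s = s.replace("T", "U")
    return RnaSequence(bases=s, id=id)
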