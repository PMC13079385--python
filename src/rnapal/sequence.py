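"""RNA sequence container and base-level helpers.

Sequences are 5'->3' strings over {A, C, G, U}. Strict Watson-Crick
complementarity (A-U, G-C) is used for palindrome identity and for
perfect-duplex region matching; G.U wobble pairs are allowed in folded
secondary structures (see :mod:`rnapal.params`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

ALPHABET = "ACGU"
BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
WC_COMPLEMENT = {"A": "U", "U": "A", "C": "G", "G": "C"}


class SequenceError(ValueError):
    """Raised for malformed sequence input."""


def complement(base: str) -> str:
    return WC_COMPLEMENT[base]


def revcomp(bases: str) -> str:
    """Strict Watson-Crick reverse complement of a 5'->3' string."""
    return "".join(WC_COMPLEMENT[b] for b in reversed(bases))


def is_wc_pair(a: str, b: str) -> bool:
    """True iff a and b form a Watson-Crick pair (no wobble)."""
    return WC_COMPLEMENT[a] == b


@dataclass(frozen=True)
class RnaSequence:
    """An identified RNA sequence, read 5'->3'.

    Parameters
    ----------
    id : str
        Short label (FASTA header word or generated name).
    bases : str
        Uppercase string over {A, C, G, U}, length >= 1.
    """

    id: str
    bases: str
    _indices: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.bases) < 1:
            raise SequenceError(f"sequence {self.id!r} is empty")
        bad = set(self.bases) - set(ALPHABET)
        if bad:
            raise SequenceError(
                f"sequence {self.id!r} contains non-RNA characters {sorted(bad)}; "
                "use convert_t=True to transliterate DNA input"
            )
        idx = np.array([BASE_INDEX[b] for b in self.bases], dtype=np.int8)
        object.__setattr__(self, "_indices", idx)

    @classmethod
    def from_string(cls, id: str, bases: str, convert_t: bool = False) -> "RnaSequence":
        """Build from raw text, normalizing case and optionally T->U."""
        s = bases.strip().upper()
        if "T" in s:
            if convert_t:
                warnings.warn(
                    f"sequence {id!r}: transliterating T -> U", stacklevel=2
                )
                s = s.replace("T", "U")
            else:
                raise SequenceError(
                    f"sequence {id!r} contains T; pass convert_t=True for DNA input"
                )
        return cls(id=id, bases=s)

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def indices(self) -> np.ndarray:
        """int8 array of base indices (A=0, C=1, G=2, U=3)."""
        return self._indices

    def region(self, start: int, length: int) -> str:
        """Bases of the half-open region [start, start+length)."""
        if start < 0 or length < 1 or start + length > len(self.bases):
            raise SequenceError(
                f"region ({start}, {length}) out of bounds for length {len(self.bases)}"
            )
        return self.bases[start : start + length]

    def reverse_complement(self, id: str | None = None) -> "RnaSequence":
        return RnaSequence(id=id or f"{self.id}_rc", bases=revcomp(self.bases))


def as_rna(seq: "RnaSequence | str", id: str = "seq") -> RnaSequence:
    """Coerce a plain string to :class:`RnaSequence` (strings are convenient in tests)."""
    if isinstance(seq, RnaSequence):
        return seq
    return RnaSequence(id=id, bases=seq.upper())
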