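"""Core sequence and coordinate types.

All internal coordinates are 0-based half-open; conversion to the 1-based
inclusive GFF3 convention happens at a single point in :mod:`cassfinder.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

_ALPHABET = frozenset("ACGTN")


class SequenceError(ValueError):
    """Raised for malformed sequences or records."""


@dataclass(frozen=True)
class Interval:
    """Half-open genomic interval: ``start`` inclusive, ``end`` exclusive."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    def length(self) -> int:
        return self.end - self.start

    def overlap(self, other: "Interval") -> int:
        """Number of shared positions (0 if disjoint)."""
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "Interval") -> bool:
        return self.start <= other.start and other.end <= self.end

    def shift(self, offset: int) -> "Interval":
        return Interval(self.start + offset, self.end + offset)


@dataclass(frozen=True)
class SequenceRecord:
    """A named uppercase DNA sequence over {A, C, G, T, N}.

    Lowercase input is folded to uppercase; any other residue is rejected.
    """

    id: str
    residues: str
    source: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceError("sequence record needs a non-empty id")
        if not self.residues:
            raise SequenceError(f"record {self.id!r}: empty sequence")
        seq = self.residues.upper()
        if set(seq) - _ALPHABET:
            bad = sorted(set(seq) - _ALPHABET)
            raise SequenceError(f"record {self.id!r}: invalid residues {bad}")
        object.__setattr__(self, "residues", seq)

    def __len__(self) -> int:
        return len(self.residues)

    def slice(self, iv: Interval, new_id: str | None = None) -> "SequenceRecord":
        if iv.end > len(self.residues):
            raise SequenceError(f"interval {iv} exceeds record {self.id!r}")
        return SequenceRecord(
            id=new_id or f"{self.id}:{iv.start}-{iv.end}",
            residues=self.residues[iv.start : iv.end],
            source=f"slice of {self.id}",
        )


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass
class AlignmentResult:
    """A pairwise alignment with its identity statistic.

    ``identity_pct`` = 100 x matched columns / columns where at least one
    sequence has a residue, with terminal-overhang columns excluded.
    Internal gap columns count in the denominator.
    """

    aligned_a: str
    aligned_b: str
    score: float
    identity_pct: float
    span_a: Interval
    span_b: Interval
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings differ in length")
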