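"""Core genomic coordinate types.

All coordinates throughout the package are BED-native: 0-based,
half-open ``[start, end)``. The single place where 1-based inclusive
coordinates appear is :func:`GenomicInterval.to_ucsc`, used only for
display strings such as ``chr2:74,872,605-75,696,338``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

__all__ = ["GenomeAssembly", "GenomicInterval"]


@dataclass(frozen=True)
class GenomeAssembly:
    """A named genome build with its chromosome lengths.

    Parameters
    ----------
    name
        Assembly label, e.g. ``"mm10"`` or ``"galGal6"``.
    chrom_sizes
        Mapping from chromosome name to its length in bp.
    """

    name: str
    chrom_sizes: Mapping[str, int]

    def __post_init__(self) -> None:
        for chrom, size in self.chrom_sizes.items():
            if size <= 0:
                raise ValueError(f"chromosome {chrom!r} has non-positive length {size}")

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_sizes

    def size(self, chrom: str) -> int:
        try:
            return self.chrom_sizes[chrom]
        except KeyError:
            raise KeyError(
                f"chromosome {chrom!r} not in assembly {self.name!r}"
            ) from None


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval (0-based start, exclusive end)."""

    chrom: str
    start: int
    end: int
    name: Optional[str] = None
    score: Optional[float] = None
    strand: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"start must be < end, got [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in (None, "+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2

    def validate(self, assembly: GenomeAssembly) -> "GenomicInterval":
        """Check the interval fits on its chromosome; return self."""
        size = assembly.size(self.chrom)
        if self.end > size:
            raise ValueError(
                f"interval {self.chrom}:{self.start}-{self.end} exceeds "
                f"chromosome length {size} in {assembly.name}"
            )
        return self

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def to_ucsc(self) -> str:
        """1-based inclusive display string, thousands-separated."""
        return f"{self.chrom}:{self.start + 1:,}-{self.end:,}"

    @classmethod
    def from_ucsc(cls, text: str, **kwargs) -> "GenomicInterval":
        """Parse ``chrom:start-end`` (1-based inclusive, commas allowed)."""
        chrom, _, span = text.partition(":")
        lo, _, hi = span.replace(",", "").partition("-")
        if not (chrom and lo and hi):
            raise ValueError(f"cannot parse locus string {text!r}")
        return cls(chrom, int(lo) - 1, int(hi), **kwargs)


def sort_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    return sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
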