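"""Genomic coordinate primitives shared by every module.

All coordinates are 0-based, half-open (BED/cooler convention). One shared
binning function maps base pairs to bin indices so that every module agrees
on which 5-kb bin a base belongs to.
"""

from __future__ import annotations

from dataclasses import dataclass

DEFAULT_BIN_SIZE = 5000
DEFAULT_TRACK_RESOLUTION = 25


@dataclass(frozen=True, order=True)
class GenomicRegion:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"empty/inverted region {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def n_bins(self, bin_size: int) -> int:
        if len(self) % bin_size != 0:
            raise ValueError(
                f"region length {len(self)} not divisible by bin size {bin_size}"
            )
        return len(self) // bin_size

    def contains(self, other: "GenomicRegion") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def overlaps(self, other: "GenomicRegion") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def shift(self, offset: int) -> "GenomicRegion":
        return GenomicRegion(self.chrom, self.start + offset, self.end + offset)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start}-{self.end}"


def bp_to_bin(pos: int, region_start: int, bin_size: int) -> int:
    """Map an absolute bp position to a bin index relative to ``region_start``.

    Shared by every module; the half-open convention means ``bp_to_bin(start)
    == 0`` and ``bp_to_bin(end - 1) == n_bins - 1``.
    """
    if pos < region_start:
        raise ValueError(f"position {pos} before region start {region_start}")
    return (pos - region_start) // bin_size


def bin_to_region(
    bin_index: int, region_start: int, bin_size: int, chrom: str
) -> GenomicRegion:
    """Genomic span of one bin."""
    start = region_start + bin_index * bin_size
    return GenomicRegion(chrom, start, start + bin_size)
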