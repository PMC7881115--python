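"""Genomic interval primitives.

All coordinates in the package are 0-based half-open ``[start, end)``.
GTF input (1-based inclusive) is converted on read; BED input is used as-is.
"""

from __future__ import annotations

from dataclasses import dataclass

VALID_STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic region ``[start, end)`` on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start} on {self.chrom}")
        if self.end <= self.start:
            raise ValueError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"unknown strand symbol {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlap_len(self, other: "GenomicInterval") -> int:
        """Length of the overlap in bp (0 if disjoint or on another chromosome)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.overlap_len(other) > 0

    def gap_to(self, other: "GenomicInterval") -> int | None:
        """Edge-to-edge gap in bp; 0 when overlapping; None across chromosomes."""
        if self.chrom != other.chrom:
            return None
        if self.overlaps(other):
            return 0
        if self.end <= other.start:
            return other.start - self.end
        return self.start - other.end

    def intersection(self, other: "GenomicInterval") -> "GenomicInterval":
        if not self.overlaps(other):
            raise ValueError("intersection of disjoint intervals")
        return GenomicInterval(
            self.chrom, max(self.start, other.start), min(self.end, other.end)
        )

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def __str__(self) -> str:  # used for deterministic region ids
        return f"{self.chrom}:{self.start}-{self.end}"


def merge_overlapping(intervals: list[GenomicInterval]) -> list[GenomicInterval]:
    """Union-merge a list of intervals into disjoint sorted intervals.

    Touching intervals (end == start) are merged as well; strand is dropped.
    """
    if not intervals:
        return []
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    out: list[GenomicInterval] = []
    cur_chrom, cur_start, cur_end = ivs[0].chrom, ivs[0].start, ivs[0].end
    for iv in ivs[1:]:
        if iv.chrom == cur_chrom and iv.start <= cur_end:
            cur_end = max(cur_end, iv.end)
        else:
            out.append(GenomicInterval(cur_chrom, cur_start, cur_end))
            cur_chrom, cur_start, cur_end = iv.chrom, iv.start, iv.end
    out.append(GenomicInterval(cur_chrom, cur_start, cur_end))
    return out
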