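"""Genomic interval primitives.

All coordinates are 0-based, half-open ``[start, end)``; GFF/GTF 1-based
closed coordinates are converted at the parsing boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Mapping, Sequence


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open interval on a chromosome.

    Parameters
    ----------
    chromosome : str
        Chromosome (or contig) name.
    start, end : int
        0-based half-open coordinates; ``end > start >= 0``.
    strand : str
        ``"+"``, ``"-"`` or ``"."`` (unknown / irrelevant).
    """

    chromosome: str
    start: int
    end: int
    strand: str = field(default=".", compare=False)

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start coordinate: {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"empty or inverted interval: [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand: {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        """Length of the overlap with ``other`` (0 if different chromosome)."""
        if self.chromosome != other.chromosome:
            return 0
        return overlap_length(self.start, self.end, other.start, other.end)

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chromosome == other.chromosome
            and self.start <= other.start
            and other.end <= self.end
        )


def overlap_length(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Overlap length of two half-open intervals on the same chromosome."""
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def merge_intervals(intervals: Iterable[GenomicInterval]) -> List[GenomicInterval]:
    """Merge overlapping or bookended intervals into a disjoint sorted union.

    Intervals on different chromosomes are merged independently; the result is
    sorted by (chromosome, start).  Strand is dropped (set to ``"."``) because
    the union of features from both strands is strand-agnostic.
    """
    by_pos = sorted(intervals, key=lambda iv: (iv.chromosome, iv.start, iv.end))
    merged: List[GenomicInterval] = []
    for iv in by_pos:
        if (
            merged
            and merged[-1].chromosome == iv.chromosome
            and iv.start <= merged[-1].end
        ):
            if iv.end > merged[-1].end:
                merged[-1] = GenomicInterval(
                    iv.chromosome, merged[-1].start, iv.end
                )
        else:
            merged.append(GenomicInterval(iv.chromosome, iv.start, iv.end))
    return merged


def interval_gaps(blocks: Sequence[GenomicInterval]) -> List[GenomicInterval]:
    """Gaps between consecutive disjoint sorted blocks on one chromosome."""
    gaps: List[GenomicInterval] = []
    for left, right in zip(blocks, blocks[1:]):
        if left.chromosome != right.chromosome:
            raise ValueError("gaps are only defined within one chromosome")
        if right.start > left.end:
            gaps.append(GenomicInterval(left.chromosome, left.end, right.start))
    return gaps


def complement_intervals(
    intervals: Iterable[GenomicInterval],
    chromosome_lengths: Mapping[str, int],
) -> List[GenomicInterval]:
    """Complement of the union of ``intervals`` within each chromosome.

    Input intervals are clipped to ``[0, length)``; chromosomes with no input
    intervals contribute their full span.  Zero-length pieces are dropped.
    """
    merged = merge_intervals(
        GenomicInterval(iv.chromosome, max(0, iv.start), min(iv.end, chromosome_lengths[iv.chromosome]))
        for iv in intervals
        if iv.chromosome in chromosome_lengths
        and max(0, iv.start) < min(iv.end, chromosome_lengths[iv.chromosome])
    )
    by_chrom: dict[str, List[GenomicInterval]] = {}
    for iv in merged:
        by_chrom.setdefault(iv.chromosome, []).append(iv)

    out: List[GenomicInterval] = []
    for chrom in sorted(chromosome_lengths):
        length = chromosome_lengths[chrom]
        cursor = 0
        for iv in by_chrom.get(chrom, []):
            if iv.start > cursor:
                out.append(GenomicInterval(chrom, cursor, iv.start))
            cursor = max(cursor, iv.end)
        if cursor < length:
            out.append(GenomicInterval(chrom, cursor, length))
    return out
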