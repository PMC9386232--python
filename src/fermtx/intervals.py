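"""Stranded genomic intervals and length arithmetic.

All coordinates are 0-based, half-open ``[start, end)``.  File formats that
use other conventions (GFF3: 1-based inclusive) convert at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Sequence, Tuple

STRANDS = ("+", "-")


@dataclass(frozen=True, order=True)
class Interval:
    """A stranded genomic interval, 0-based half-open."""

    contig: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.contig}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_length(self, other: "Interval") -> int:
        """Number of shared bases (strand-agnostic; 0 on different contigs)."""
        if self.contig != other.contig:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


def jaccard(a: Interval, b: Interval) -> float:
    """Jaccard similarity of two intervals: |a ∩ b| / |a ∪ b|.

    The union is the total number of distinct bases covered by either
    interval.  Intervals on different contigs or strands share no bases and
    score 0.
    """
    if a.contig != b.contig or a.strand != b.strand:
        return 0.0
    inter = a.overlap_length(b)
    if inter == 0:
        return 0.0
    union = a.length + b.length - inter
    return inter / union


def overlap_fraction(query: Interval, target: Interval, denominator: str = "query") -> float:
    """Percent of ``denominator`` interval covered by the other, 1 decimal.

    Strand-agnostic: antisense overlaps count.  ``denominator`` selects
    whether the overlap is expressed relative to the query or the target
    length.
    """
    if denominator not in ("query", "target"):
        raise ValueError("denominator must be 'query' or 'target'")
    inter = query.overlap_length(target)
    denom = query.length if denominator == "query" else target.length
    return round(100.0 * inter / denom, 1)


def merge_intervals(intervals: Iterable[Tuple[int, int]]) -> List[Tuple[int, int]]:
    """Merge overlapping/adjacent (start, end) pairs into maximal runs."""
    ivs = sorted(intervals)
    merged: List[Tuple[int, int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            if e > merged[-1][1]:
                merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


def complement_intervals(
    occupied: Sequence[Tuple[int, int]], length: int
) -> List[Tuple[int, int]]:
    """Maximal (start, end) runs of ``[0, length)`` not covered by ``occupied``."""
    gaps: List[Tuple[int, int]] = []
    pos = 0
    for s, e in merge_intervals(occupied):
        if s > pos:
            gaps.append((pos, s))
        pos = max(pos, e)
    if pos < length:
        gaps.append((pos, length))
    return gaps
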