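"""Genomic interval primitives and arithmetic.

All coordinates are 0-based half-open (BED-native).  Interval arithmetic
(merge, complement, coverage) is done on integer numpy arrays per
chromosome; the operations here are the building blocks for nucleosome
region sets, NDR calling and motif base-pair counting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "NarrowPeakRecord",
    "FragmentRecord",
    "merge_intervals",
    "complement_intervals",
    "total_length",
    "covered_length",
    "overlap_fraction",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval.

    ``strand`` is one of ``+``, ``-`` or ``.`` (unstranded, the default).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class NarrowPeakRecord:
    """One ENCODE narrowPeak record (10-column BED6+4).

    ``summit_offset`` is the offset of the point-source summit from
    ``start``, or -1 when no summit was called.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = "."
    score: float = 0.0
    signal_value: float = 0.0
    p_score: float = -1.0
    q_score: float = -1.0
    summit_offset: int = -1

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid peak {self.chrom}:{self.start}-{self.end}"
            )
        if self.summit_offset != -1 and not (
            0 <= self.summit_offset < self.end - self.start
        ):
            raise ValueError(
                f"summit offset {self.summit_offset} outside peak of length "
                f"{self.end - self.start}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def summit(self) -> int:
        """Absolute summit coordinate; interval midpoint when uncalled."""
        if self.summit_offset >= 0:
            return self.start + self.summit_offset
        return (self.start + self.end - 1) // 2

    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)


@dataclass(frozen=True)
class FragmentRecord:
    """One sequenced mono-nucleosome fragment (a proper read pair)."""

    chrom: str
    start: int
    end: int
    replicate_id: str = "rep1"

    def __post_init__(self) -> None:
        if self.end - self.start <= 0:
            raise ValueError(
                f"fragment {self.chrom}:{self.start}-{self.end} has "
                "non-positive length"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def midpoint(self) -> int:
        # left of the two central bases for even lengths
        return (self.start + self.end - 1) // 2


def _as_arrays(intervals: Iterable) -> tuple[np.ndarray, np.ndarray]:
    starts = []
    ends = []
    for iv in intervals:
        starts.append(iv.start)
        ends.append(iv.end)
    return np.asarray(starts, dtype=np.int64), np.asarray(ends, dtype=np.int64)


def merge_intervals(intervals: Sequence) -> list[tuple[int, int]]:
    """Merge overlapping/adjacent intervals of one chromosome.

    Returns sorted, disjoint ``(start, end)`` tuples.  Book-ended
    intervals (end == next start) are merged so the result is a minimal
    cover of the input's footprint.
    """
    starts, ends = _as_arrays(intervals)
    if starts.size == 0:
        return []
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    merged: list[tuple[int, int]] = []
    cur_s, cur_e = int(starts[0]), int(ends[0])
    for s, e in zip(starts[1:], ends[1:]):
        if s <= cur_e:
            cur_e = max(cur_e, int(e))
        else:
            merged.append((cur_s, cur_e))
            cur_s, cur_e = int(s), int(e)
    merged.append((cur_s, cur_e))
    return merged


def complement_intervals(
    intervals: Sequence, chrom_length: int
) -> list[tuple[int, int]]:
    """Maximal sub-intervals of ``[0, chrom_length)`` not covered by input."""
    out: list[tuple[int, int]] = []
    pos = 0
    for s, e in merge_intervals(intervals):
        s = max(s, 0)
        e = min(e, chrom_length)
        if s > pos:
            out.append((pos, s))
        pos = max(pos, e)
    if pos < chrom_length:
        out.append((pos, chrom_length))
    return out


def total_length(merged: Iterable[tuple[int, int]]) -> int:
    return sum(e - s for s, e in merged)


def covered_length(
    query: Iterable[tuple[int, int]], subject: Sequence[tuple[int, int]]
) -> int:
    """Base pairs of ``query`` covered by the merged ``subject`` intervals.

    Both arguments are (start, end) tuples; ``subject`` must already be
    sorted and disjoint (output of :func:`merge_intervals`).
    """
    if not subject:
        return 0
    sub_starts = np.array([s for s, _ in subject], dtype=np.int64)
    sub_ends = np.array([e for _, e in subject], dtype=np.int64)
    covered = 0
    for qs, qe in query:
        # subjects possibly overlapping [qs, qe)
        lo = int(np.searchsorted(sub_ends, qs, side="right"))
        hi = int(np.searchsorted(sub_starts, qe, side="left"))
        for i in range(lo, hi):
            covered += min(qe, int(sub_ends[i])) - max(qs, int(sub_starts[i]))
    return covered


def overlap_fraction(region: GenomicInterval, others: Sequence) -> float:
    """Fraction of ``region`` covered by the union of ``others``.

    ``others`` are intervals on the same chromosome as ``region``;
    intervals on different chromosomes are ignored.
    """
    same = [iv for iv in others if iv.chrom == region.chrom]
    merged = merge_intervals(same)
    bp = covered_length([(region.start, region.end)], merged)
    return bp / region.length
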