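"""Nucleosome dyad calling from mono-nucleosome fragment midpoints.

The dyad of a nucleosome is the central base pair of its ~147-bp DNA.
Midpoints of tightly size-selected fragments (146-148 bp) estimate dyad
positions; per-base midpoint counts are smoothed with a triweight kernel
of small bandwidth (h = 15 bp), local maxima of the smoothed track at
least 150 bp apart mark candidate nucleosomes, and within a 60-bp window
around each maximum the raw-count argmax becomes the representative
dyad.  Each representative dyad defines a 147-bp nucleosome region (NR).
Nucleosome-depleted regions (NDRs) are the genomic stretches covered by
no 120-180-bp fragment in any replicate.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .intervals import (
    FragmentRecord,
    GenomicInterval,
    complement_intervals,
    merge_intervals,
)

logger = logging.getLogger(__name__)

__all__ = [
    "DyadCountTrack",
    "SmoothedTrack",
    "RepresentativeDyad",
    "NucleosomeRegionSet",
    "fragments_to_dyad_counts",
    "triweight_kernel",
    "smooth_dyad_counts",
    "find_local_maxima",
    "select_representative_dyads",
    "call_nucleosome_regions",
    "call_ndrs",
    "compute_occupancy",
    "call_dyads",
]


@dataclass
class DyadCountTrack:
    """Integer dyad-midpoint counts d(j) at every base of one chromosome."""

    chrom: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1:
            raise ValueError("counts must be a 1-D array")
        if (self.counts < 0).any():
            raise ValueError("dyad counts must be non-negative")

    @property
    def chrom_length(self) -> int:
        return len(self.counts)


@dataclass
class SmoothedTrack:
    """Kernel-smoothed dyad counts D(i) with bandwidth h."""

    chrom: str
    values: np.ndarray
    bandwidth: int


@dataclass(frozen=True)
class RepresentativeDyad:
    chrom: str
    position: int
    raw_count: int
    nearest_maximum: int

    def __post_init__(self) -> None:
        if self.raw_count < 1:
            raise ValueError("representative dyad needs raw_count >= 1")


@dataclass
class NucleosomeRegionSet:
    """Representative dyads with their 147-bp nucleosome regions."""

    dyads: list[RepresentativeDyad]
    regions: list[GenomicInterval]
    n_clipped: int = 0


def fragments_to_dyad_counts(
    fragments: Iterable[FragmentRecord],
    chrom_sizes: Mapping[str, int],
    min_len: int = 146,
    max_len: int = 148,
) -> dict[str, DyadCountTrack]:
    """Accumulate fragment midpoints into per-chromosome count tracks.

    Only fragments with ``min_len <= length <= max_len`` contribute; the
    midpoint of an even-length fragment is the left of its two central
    bases (``floor((start + end - 1) / 2)``).
    """
    tracks = {
        chrom: np.zeros(size, dtype=np.int64)
        for chrom, size in chrom_sizes.items()
    }
    n_out_of_bounds = 0
    for frag in fragments:
        if not (min_len <= frag.length <= max_len):
            continue
        counts = tracks.get(frag.chrom)
        if counts is None:
            raise ValueError(f"no chromosome size for {frag.chrom}")
        if frag.start < 0 or frag.end > len(counts):
            n_out_of_bounds += 1
            continue
        counts[frag.midpoint()] += 1
    if n_out_of_bounds:
        logger.info(
            "skipped %d fragments outside chromosome bounds", n_out_of_bounds
        )
    return {
        chrom: DyadCountTrack(chrom, counts)
        for chrom, counts in tracks.items()
    }


def triweight_kernel(u, h: float):
    """Triweight weight ``(1 - (u/h)^2)^3`` on ``|u| <= h``, else 0."""
    if h <= 0:
        raise ValueError("bandwidth h must be positive")
    u = np.asarray(u, dtype=float)
    w = np.where(np.abs(u) <= h, (1.0 - (u / h) ** 2) ** 3, 0.0)
    return w if w.ndim else float(w)


def smooth_dyad_counts(track: DyadCountTrack, h: int = 15) -> SmoothedTrack:
    """Convolve the dyad-count track with the triweight kernel.

    ``D(i) = (1 / (N h)) * sum_j K(i - j) d(j)`` with N the chromosome
    length; the global 1/(N h) factor is a monotone scale and cannot move
    any maximum.
    """
    kernel = triweight_kernel(np.arange(-h, h + 1), h)
    smoothed = np.convolve(track.counts.astype(float), kernel, mode="same")
    smoothed /= track.chrom_length * h
    return SmoothedTrack(track.chrom, smoothed, h)


def _plateau_maxima(values: np.ndarray) -> list[int]:
    """Leftmost index of every positive plateau strictly above both
    neighbours (chromosome edges count as lower ground)."""
    n = len(values)
    maxima: list[int] = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and values[j + 1] == values[i]:
            j += 1
        left_ok = i == 0 or values[i - 1] < values[i]
        right_ok = j == n - 1 or values[j + 1] < values[i]
        if left_ok and right_ok and values[i] > 0:
            maxima.append(i)
        i = j + 1
    return maxima


def find_local_maxima(
    smoothed: SmoothedTrack, min_sep: int = 150
) -> list[int]:
    """Local maxima of the smoothed track, at least ``min_sep`` bp apart.

    Plateaus yield their leftmost base.  When candidates are closer than
    ``min_sep``, they are retained greedily in order of descending
    smoothed value (ties broken toward the lower coordinate).
    """
    if min_sep < 1:
        raise ValueError("min_sep must be >= 1")
    candidates = _plateau_maxima(smoothed.values)
    order = sorted(candidates, key=lambda i: (-smoothed.values[i], i))
    kept: list[int] = []
    for pos in order:
        idx = bisect.bisect_left(kept, pos)
        if idx > 0 and pos - kept[idx - 1] < min_sep:
            continue
        if idx < len(kept) and kept[idx] - pos < min_sep:
            continue
        kept.insert(idx, pos)
    return kept


def select_representative_dyads(
    raw: DyadCountTrack, maxima: Sequence[int], window: int = 60
) -> list[RepresentativeDyad]:
    """Pick one representative dyad per smoothed maximum.

    Within the half-open ``window``-bp window ``[m - w/2, m + w/2)``
    around maximum ``m``, the position with the highest raw dyad count
    wins; ties go to the position closest to ``m``, then to the lower
    coordinate.  Windows containing no raw counts yield no dyad.
    """
    half = window // 2
    dyads: list[RepresentativeDyad] = []
    for m in maxima:
        lo = max(m - half, 0)
        hi = min(m + half, raw.chrom_length)
        segment = raw.counts[lo:hi]
        if segment.size == 0 or segment.max() == 0:
            continue
        best = segment.max()
        positions = np.flatnonzero(segment == best) + lo
        # closest to the maximum, then lowest coordinate
        pos = min(positions, key=lambda p: (abs(p - m), p))
        dyads.append(
            RepresentativeDyad(raw.chrom, int(pos), int(best), int(m))
        )
    return dyads


def call_nucleosome_regions(
    dyads: Sequence[RepresentativeDyad],
    chrom_sizes: Mapping[str, int],
    flank: int = 73,
) -> NucleosomeRegionSet:
    """147-bp NRs ``[dyad - flank, dyad + flank + 1)``; regions that would
    extend past a chromosome edge are dropped (and counted)."""
    kept: list[RepresentativeDyad] = []
    regions: list[GenomicInterval] = []
    n_clipped = 0
    for dyad in dyads:
        start = dyad.position - flank
        end = dyad.position + flank + 1
        if start < 0 or end > chrom_sizes[dyad.chrom]:
            n_clipped += 1
            continue
        kept.append(dyad)
        regions.append(GenomicInterval(dyad.chrom, start, end))
    if n_clipped:
        logger.info("dropped %d edge-clipped nucleosome regions", n_clipped)
    return NucleosomeRegionSet(kept, regions, n_clipped)


def call_ndrs(
    fragments: Iterable[FragmentRecord],
    chrom_sizes: Mapping[str, int],
    min_len: int = 120,
    max_len: int = 180,
) -> list[GenomicInterval]:
    """Nucleosome-depleted regions: maximal intervals covered by no
    mono-nucleosome (120-180 bp) fragment in any replicate (fragments are
    pooled across replicates before taking the complement)."""
    by_chrom: dict[str, list[FragmentRecord]] = {c: [] for c in chrom_sizes}
    for frag in fragments:
        if min_len <= frag.length <= max_len and frag.chrom in by_chrom:
            by_chrom[frag.chrom].append(frag)
    ndrs: list[GenomicInterval] = []
    for chrom, size in chrom_sizes.items():
        for s, e in complement_intervals(by_chrom[chrom], size):
            ndrs.append(GenomicInterval(chrom, s, e))
    return ndrs


def compute_occupancy(
    fragments: Iterable[FragmentRecord],
    chrom_sizes: Mapping[str, int],
    min_len: int = 120,
    max_len: int = 180,
) -> dict[str, np.ndarray]:
    """Per-base mono-nucleosome fragment coverage (nucleosome occupancy)."""
    diff = {
        chrom: np.zeros(size + 1, dtype=np.int64)
        for chrom, size in chrom_sizes.items()
    }
    for frag in fragments:
        if not (min_len <= frag.length <= max_len):
            continue
        d = diff.get(frag.chrom)
        if d is None:
            continue
        s = max(frag.start, 0)
        e = min(frag.end, len(d) - 1)
        if s < e:
            d[s] += 1
            d[e] -= 1
    return {chrom: np.cumsum(d[:-1]) for chrom, d in diff.items()}


def call_dyads(
    fragments: Sequence[FragmentRecord],
    chrom_sizes: Mapping[str, int],
    h: int = 15,
    min_sep: int = 150,
    window: int = 60,
    flank: int = 73,
    min_len: int = 146,
    max_len: int = 148,
) -> NucleosomeRegionSet:
    """Full dyad-calling pass over all chromosomes: count midpoints,
    smooth, find maxima, pick representative dyads, emit NRs."""
    tracks = fragments_to_dyad_counts(
        fragments, chrom_sizes, min_len=min_len, max_len=max_len
    )
    all_dyads: list[RepresentativeDyad] = []
    for chrom in chrom_sizes:
        track = tracks[chrom]
        if track.counts.sum() == 0:
            continue
        smoothed = smooth_dyad_counts(track, h)
        maxima = find_local_maxima(smoothed, min_sep)
        all_dyads.extend(select_representative_dyads(track, maxima, window))
    return call_nucleosome_regions(all_dyads, chrom_sizes, flank)
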