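"""Open-chromatin and enhancer region annotation.

Open chromatin is defined from DNase-seq narrowPeak summits flanked by
1 kb on each side; active enhancers are the open regions overlapping
both H3K27ac and H3K4me1 peaks.  Comparing one cell line's open (or
enhancer) regions against other cell lines yields conserved regions
(> 80% of the region covered in at least one other line) and
differentially open regions (< 20% covered in every comparator line).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

from .intervals import (
    GenomicInterval,
    NarrowPeakRecord,
    merge_intervals,
    covered_length,
)

__all__ = [
    "OpenChromatinSet",
    "RegionClass",
    "RegionClassification",
    "call_open_chromatin",
    "call_active_enhancers",
    "classify_open_regions",
    "classify_enhancers",
]


@dataclass
class OpenChromatinSet:
    cell_line: str
    regions: list[GenomicInterval] = field(default_factory=list)


class RegionClass(str, Enum):
    CONSERVED = "conserved_open"
    DIFFERENTIAL = "differentially_open"
    UNCLASSIFIED = "unclassified"


@dataclass
class RegionClassification:
    """Per-region class labels plus the max overlap fraction observed."""

    classes: list[RegionClass]
    max_fractions: list[float]
    regions: list[GenomicInterval]

    def regions_of(self, cls: RegionClass) -> list[GenomicInterval]:
        return [r for r, c in zip(self.regions, self.classes) if c is cls]


def call_open_chromatin(
    peaks: Sequence[NarrowPeakRecord],
    chrom_sizes: Mapping[str, int],
    cell_line: str = "",
    flank: int = 1000,
) -> OpenChromatinSet:
    """Open-chromatin regions: DNase peak summits flanked by ``flank`` bp.

    Each region is ``[summit - flank, summit + flank + 1)`` (2001 bp for
    the default flank), clipped at chromosome edges; uncalled summits
    fall back to the peak-interval midpoint.  Overlapping regions are
    kept as-is, not merged.
    """
    regions = []
    for peak in peaks:
        c = peak.summit()
        start = max(c - flank, 0)
        end = min(c + flank + 1, chrom_sizes[peak.chrom])
        regions.append(GenomicInterval(peak.chrom, start, end))
    return OpenChromatinSet(cell_line, regions)


def _overlaps_any(
    region: GenomicInterval, merged_by_chrom: Mapping[str, list]
) -> bool:
    merged = merged_by_chrom.get(region.chrom, [])
    return covered_length([(region.start, region.end)], merged) > 0


def _merge_by_chrom(peaks: Sequence) -> dict[str, list]:
    by_chrom: dict[str, list] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append(p)
    return {c: merge_intervals(ps) for c, ps in by_chrom.items()}


def call_active_enhancers(
    open_set: OpenChromatinSet,
    h3k27ac: Sequence[NarrowPeakRecord],
    h3k4me1: Sequence[NarrowPeakRecord],
) -> list[GenomicInterval]:
    """Open regions overlapping (>= 1 bp) both H3K27ac and H3K4me1 peaks."""
    ac = _merge_by_chrom(h3k27ac)
    me1 = _merge_by_chrom(h3k4me1)
    return [
        r
        for r in open_set.regions
        if _overlaps_any(r, ac) and _overlaps_any(r, me1)
    ]


def classify_open_regions(
    target: OpenChromatinSet,
    others: Sequence[OpenChromatinSet],
    conserved_min: float = 0.8,
    differential_max: float = 0.2,
) -> RegionClassification:
    """Classify each target region by its overlap with other cell lines.

    The overlap fraction of region ``r`` against a comparator is the
    fraction of ``r``'s bases covered by the union of that comparator's
    regions.  A region is conserved when the fraction exceeds
    ``conserved_min`` for at least one comparator, differentially open
    when it is below ``differential_max`` against every comparator, and
    unclassified otherwise.
    """
    if not others:
        raise ValueError("need at least one comparator cell line")
    if not (0 <= differential_max < conserved_min <= 1):
        raise ValueError(
            "thresholds must satisfy 0 <= differential_max < conserved_min <= 1"
        )
    merged_per_other = [_merge_by_chrom(o.regions) for o in others]
    classes: list[RegionClass] = []
    max_fracs: list[float] = []
    for r in target.regions:
        fracs = [
            covered_length([(r.start, r.end)], m.get(r.chrom, [])) / r.length
            for m in merged_per_other
        ]
        fmax = max(fracs)
        if fmax > conserved_min:
            cls = RegionClass.CONSERVED
        elif fmax < differential_max:
            cls = RegionClass.DIFFERENTIAL
        else:
            cls = RegionClass.UNCLASSIFIED
        classes.append(cls)
        max_fracs.append(fmax)
    return RegionClassification(classes, max_fracs, list(target.regions))


def classify_enhancers(
    target_enhancers: Sequence[GenomicInterval],
    other_enhancers: Sequence[Sequence[GenomicInterval]],
    cell_line: str = "",
    conserved_min: float = 0.8,
    differential_max: float = 0.2,
) -> RegionClassification:
    """Same contract as :func:`classify_open_regions`, on enhancer sets."""
    target = OpenChromatinSet(cell_line, list(target_enhancers))
    others = [
        OpenChromatinSet(f"other{i}", list(regs))
        for i, regs in enumerate(other_enhancers)
    ]
    return classify_open_regions(
        target, others, conserved_min, differential_max
    )
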