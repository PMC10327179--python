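"""Dyad-centered profiles and their summary statistics.

A motif profile counts, at every signed offset from the aligned
nucleosome dyads, how many motif base pairs of one TF map there; the
occupancy profile is the mean mono-nucleosome fragment coverage over the
same dyads.  Summary statistics implemented here: Pearson correlation
between motif profile and occupancy (+/-400 bp, the nucleosome-binder
call), the end/dyad binding ratio over superhelical-location windows
(SHL +/-5.5..7 vs 0..+/-1.5 at 10.5 bp per SHL), the symmetry
correlation between the two nucleosomal halves, and WW/SS / YY/RR
dinucleotide phase profiles of nucleosome regions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .dyads import NucleosomeRegionSet
from .scan import AssignedHit

__all__ = [
    "MotifProfile",
    "OccupancyProfile",
    "DinucleotideProfile",
    "build_motif_profile",
    "build_occupancy_profile",
    "build_dinucleotide_profile",
    "minmax_normalize",
    "occupancy_correlation",
    "OccupancyCall",
    "end_dyad_ratio",
    "symmetry_correlation",
    "DINUCLEOTIDE_CLASSES",
]

# W = A/T, S = G/C (weak/strong); R = A/G, Y = C/T (purine/pyrimidine)
DINUCLEOTIDE_CLASSES: dict[str, frozenset[str]] = {
    "WW/SS": frozenset(
        a + b
        for a in "ACGT"
        for b in "ACGT"
        if (a in "AT" and b in "AT") or (a in "GC" and b in "GC")
    ),
    "YY/RR": frozenset(
        a + b
        for a in "ACGT"
        for b in "ACGT"
        if (a in "CT" and b in "CT") or (a in "AG" and b in "AG")
    ),
}


@dataclass
class MotifProfile:
    """Motif base-pair counts per signed offset from the dyad."""

    tf_name: str
    counts: np.ndarray  # length 2 * half_width + 1
    half_width: int
    n_hits: int = 0
    cell_line: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if len(self.counts) != 2 * self.half_width + 1:
            raise ValueError("counts length must be 2 * half_width + 1")
        if (self.counts < 0).any():
            raise ValueError("profile counts must be non-negative")

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(-self.half_width, self.half_width + 1)

    def __getitem__(self, offset: int) -> int:
        return self.counts[offset + self.half_width]

    def window_sum(self, lo: int, hi: int) -> float:
        """Sum of counts over |offset| in [lo, hi] (both sides)."""
        c = self.counts
        hw = self.half_width
        lo_i, hi_i = max(lo, 0), min(hi, hw)
        if lo_i > hi_i:
            return 0.0
        total = float(c[hw + lo_i : hw + hi_i + 1].sum())
        if lo_i == 0:  # don't count the dyad base twice
            lo_neg = max(lo_i, 1)
        else:
            lo_neg = lo_i
        if lo_neg <= hi_i:
            total += float(c[hw - hi_i : hw - lo_neg + 1].sum())
        return total


@dataclass
class OccupancyProfile:
    """Mean fragment coverage per signed offset from the aligned dyads."""

    values: np.ndarray
    half_width: int
    n_dyads: int = 0

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(-self.half_width, self.half_width + 1)


@dataclass
class DinucleotideProfile:
    """Per-offset frequency of one dinucleotide class over aligned NRs.

    Offsets run from -flank to flank - 1: the dinucleotide at offset o
    starts at dyad + o, so the last NR base has no dinucleotide.
    """

    dinucleotide_class: str
    frequencies: np.ndarray
    flank: int
    n_regions: int

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(-self.flank, self.flank)


def build_motif_profile(
    assigned_hits: Sequence[AssignedHit],
    half_width: int = 1000,
    tf_name: str | None = None,
    cell_line: str = "",
) -> MotifProfile:
    """Count motif base pairs at each offset from the assigned dyads.

    Every base of every hit contributes at its genomic offset from the
    hit's dyad; bases falling outside +/- ``half_width`` are dropped.
    """
    counts = np.zeros(2 * half_width + 1, dtype=np.int64)
    names = set()
    for ah in assigned_hits:
        names.add(ah.hit.tf_name)
        lo = ah.hit.start - ah.dyad_position
        hi = ah.hit.end - ah.dyad_position  # exclusive
        lo_c = max(lo, -half_width)
        hi_c = min(hi, half_width + 1)
        if lo_c < hi_c:
            counts[lo_c + half_width : hi_c + half_width] += 1
    if tf_name is None:
        tf_name = names.pop() if len(names) == 1 else "mixed"
    return MotifProfile(
        tf_name, counts, half_width, n_hits=len(assigned_hits),
        cell_line=cell_line,
    )


def build_occupancy_profile(
    occupancy: Mapping[str, np.ndarray],
    dyads: Sequence,
    half_width: int = 1000,
) -> OccupancyProfile:
    """Mean per-base fragment coverage around the given dyads.

    Dyads whose window extends past a chromosome end are skipped so every
    offset averages over the same number of nucleosomes.
    """
    total = np.zeros(2 * half_width + 1, dtype=float)
    n = 0
    for d in dyads:
        track = occupancy.get(d.chrom)
        if track is None:
            continue
        lo = d.position - half_width
        hi = d.position + half_width + 1
        if lo < 0 or hi > len(track):
            continue
        total += track[lo:hi]
        n += 1
    return OccupancyProfile(total / n if n else total, half_width, n)


def build_dinucleotide_profile(
    genome: Mapping[str, str],
    nr_set: NucleosomeRegionSet,
    dinucleotide_class: str = "WW/SS",
    flank: int = 73,
) -> DinucleotideProfile:
    """Frequency of a dinucleotide class at each offset over aligned NRs."""
    members = DINUCLEOTIDE_CLASSES[dinucleotide_class]
    n_offsets = 2 * flank
    hits = np.zeros(n_offsets, dtype=np.int64)
    n_regions = 0
    for dyad in nr_set.dyads:
        seq = genome[dyad.chrom]
        start = dyad.position - flank
        if start < 0 or dyad.position + flank + 1 > len(seq):
            continue
        window = seq[start : start + 2 * flank + 1].upper()
        n_regions += 1
        for o in range(n_offsets):
            if window[o : o + 2] in members:
                hits[o] += 1
    freqs = hits / n_regions if n_regions else hits.astype(float)
    return DinucleotideProfile(dinucleotide_class, freqs, flank, n_regions)


def minmax_normalize(values: np.ndarray) -> np.ndarray:
    """Scale to [0, 1] as (x - min) / (max - min); constant input errors."""
    values = np.asarray(values, dtype=float)
    vmin, vmax = values.min(), values.max()
    if vmax == vmin:
        raise ValueError("min-max normalization undefined for constant input")
    return (values - vmin) / (vmax - vmin)


@dataclass(frozen=True)
class OccupancyCall:
    pcc: float
    p_value: float
    potential_nucleosome_binder: bool
    canonical_like: bool


def occupancy_correlation(
    motif_profile: MotifProfile,
    occupancy_profile: OccupancyProfile,
    half_width: int = 400,
    binder_min_pcc: float = 0.2,
    canonical_max_pcc: float = -0.4,
    p_max: float = 0.05,
) -> OccupancyCall | None:
    """Pearson correlation of motif counts vs occupancy over +/-400 bp.

    A TF is flagged a potential nucleosome binder at PCC >= 0.2 with
    p < 0.05, and canonical-like at PCC <= -0.4 with p < 0.05.  Returns
    None (no call) when either vector has zero variance.
    """
    for prof in (motif_profile, occupancy_profile):
        if prof.half_width < half_width:
            raise ValueError("profiles must cover the correlation window")
    m = motif_profile.counts[
        motif_profile.half_width - half_width :
        motif_profile.half_width + half_width + 1
    ].astype(float)
    o = occupancy_profile.values[
        occupancy_profile.half_width - half_width :
        occupancy_profile.half_width + half_width + 1
    ]
    if np.ptp(m) == 0 or np.ptp(o) == 0:
        return None
    pcc, p = stats.pearsonr(m, o)
    return OccupancyCall(
        float(pcc),
        float(p),
        potential_nucleosome_binder=bool(pcc >= binder_min_pcc and p < p_max),
        canonical_like=bool(pcc <= canonical_max_pcc and p < p_max),
    )


def end_dyad_ratio(
    motif_profile: MotifProfile, bp_per_shl: float = 10.5
) -> float | None:
    """End/dyad binding ratio R_end/dyad.

    Motif base pairs at the DNA-end superhelical locations (|SHL| in
    [5.5, 7], i.e. |offset| in [58, 73] bp at 10.5 bp/SHL) divided by
    those near the dyad (|SHL| <= 1.5, |offset| <= 16 bp).  SHL 7 is the
    end of the wrapped DNA, so the end window is capped at the 73-bp
    edge of the 147-bp nucleosome.  Returns None (no call) when the dyad
    window is empty.
    """
    end_lo = round(5.5 * bp_per_shl)
    end_hi = min(round(7.0 * bp_per_shl), 73)
    dyad_hi = round(1.5 * bp_per_shl)
    if motif_profile.half_width < end_hi:
        raise ValueError("profile too narrow for the end window")
    dyad_sum = motif_profile.window_sum(0, dyad_hi)
    if dyad_sum == 0:
        return None
    return motif_profile.window_sum(end_lo, end_hi) / dyad_sum


def symmetry_correlation(
    motif_profile: MotifProfile, half_width: int = 73
) -> float | None:
    """PCC between the two nucleosomal halves of the profile.

    Compares counts at offsets +1..+half_width with the mirrored
    -1..-half_width; None when either half has zero variance (structural
    two-fold symmetry of the nucleosome predicts a high value for
    well-sampled profiles).
    """
    hw = motif_profile.half_width
    if hw < half_width:
        raise ValueError("profile too narrow for symmetry window")
    plus = motif_profile.counts[hw + 1 : hw + half_width + 1].astype(float)
    minus = motif_profile.counts[hw - half_width : hw][::-1].astype(float)
    if np.ptp(plus) == 0 or np.ptp(minus) == 0:
        return None
    return float(stats.pearsonr(plus, minus)[0])
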