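"""Position-weight-matrix scanning of ChIP-seq peak sequences.

Scoring follows the standard log-odds formulation: a position frequency
matrix is turned into log2 likelihood ratios against a 0-order
background, every window on both strands of each peak is scored, and a
window is a motif hit when the exact p-value of its score under the
background model falls below the threshold (default 1e-4).  P-values
come from a dynamic program over integer-discretized per-position
scores, which for short motifs agrees exactly with enumerating all 4^L
words at the discretization resolution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io import BASES, PositionFrequencyMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "PositionWeightMatrix",
    "MotifHit",
    "AssignedHit",
    "ScoreDistribution",
    "pfm_to_pwm",
    "score_distribution",
    "scan_sequence",
    "scan_peaks",
    "merge_tf_hits",
    "assign_hits_to_dyads",
]

_ENCODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i


def encode_sequence(seq: str) -> np.ndarray:
    """A/C/G/T -> 0..3; any other character (N, gaps) -> -1."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class PositionWeightMatrix:
    """Log2-odds scores per (base, motif position) with its background."""

    tf_name: str
    log_likelihood_ratios: np.ndarray  # shape (4, L)
    background: np.ndarray  # 4 probabilities summing to 1
    pseudocount: float

    def __post_init__(self) -> None:
        llr = np.asarray(self.log_likelihood_ratios, dtype=float)
        bg = np.asarray(self.background, dtype=float)
        object.__setattr__(self, "log_likelihood_ratios", llr)
        object.__setattr__(self, "background", bg)
        if not np.isfinite(llr).all():
            raise ValueError("PWM entries must be finite")
        if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0):
            raise ValueError("background must be 4 probabilities summing to 1")

    @property
    def length(self) -> int:
        return self.log_likelihood_ratios.shape[1]

    def max_score(self) -> float:
        return float(self.log_likelihood_ratios.max(axis=0).sum())

    def reverse_complement(self) -> "PositionWeightMatrix":
        return PositionWeightMatrix(
            self.tf_name,
            self.log_likelihood_ratios[::-1, ::-1],
            self.background[::-1],
            self.pseudocount,
        )


@dataclass(frozen=True)
class MotifHit:
    """One PWM match, always reported in plus-strand coordinates."""

    chrom: str
    start: int
    end: int
    strand: str
    score: float
    p_value: float
    tf_name: str
    source_peak: str = "."

    @property
    def length(self) -> int:
        return self.end - self.start

    def center(self) -> int:
        return (self.start + self.end - 1) // 2


@dataclass(frozen=True)
class AssignedHit:
    """A motif hit mapped to its closest nucleosome dyad."""

    hit: MotifHit
    dyad_position: int
    center_offset: int  # hit center minus dyad position, signed


def pfm_to_pwm(
    pfm: PositionFrequencyMatrix,
    pseudocount: float = 0.1,
    background: Sequence[float] | None = None,
) -> PositionWeightMatrix:
    """Convert observed counts to log2-odds scores.

    ``entry(b, k) = log2(((n_bk + pc * bg_b) / (N_k + pc)) / bg_b)`` with
    ``N_k`` the column sum — the pseudocount is distributed over bases in
    proportion to the background, as FIMO does.
    """
    bg = (
        np.full(4, 0.25)
        if background is None
        else np.asarray(background, dtype=float)
    )
    if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0) or (bg <= 0).any():
        raise ValueError("background must be 4 positive probabilities summing to 1")
    counts = pfm.counts
    col_sums = counts.sum(axis=0)
    if (col_sums <= 0).any():
        raise ValueError("PFM has a zero-sum column")
    prob = (counts + pseudocount * bg[:, None]) / (col_sums + pseudocount)
    llr = np.log2(prob / bg[:, None])
    return PositionWeightMatrix(pfm.tf_name, llr, bg, pseudocount)


class ScoreDistribution:
    """Exact null distribution of PWM scores over integer-discretized bins.

    Per motif position the four scores are shifted by the column minimum
    and scaled so the largest per-column integer is ``granularity``; the
    distribution of the integer total under the i.i.d. background is
    built by dynamic programming (one convolution per column).
    """

    def __init__(self, pwm: PositionWeightMatrix, granularity: int = 1000):
        llr = pwm.log_likelihood_ratios
        col_min = llr.min(axis=0)
        col_max = llr.max(axis=0)
        max_range = float((col_max - col_min).max())
        self._scale = granularity / max_range if max_range > 0 else 1.0
        self._offset = float(col_min.sum())
        int_scores = np.rint((llr - col_min) * self._scale).astype(np.int64)
        max_total = int(int_scores.max(axis=0).sum())
        dist = np.zeros(max_total + 1)
        dist[0] = 1.0
        for k in range(pwm.length):
            new = np.zeros_like(dist)
            for b in range(4):
                s = int_scores[b, k]
                new[s:] += pwm.background[b] * dist[: len(dist) - s]
            dist = new
        # survival function: P(integer score >= i)
        self._sf = np.minimum(dist[::-1].cumsum()[::-1], 1.0)

    def _to_int(self, score: float) -> int:
        return int(np.rint((score - self._offset) * self._scale))

    def p_value(self, score: float) -> float:
        """P(random background L-mer scores >= ``score``)."""
        i = self._to_int(score)
        if i < 0:
            return 1.0
        if i >= len(self._sf):
            return 0.0
        return float(self._sf[i])

    def p_values(self, scores: np.ndarray) -> np.ndarray:
        finite = np.isfinite(scores)
        raw = np.rint((np.where(finite, scores, 0.0) - self._offset)
                      * self._scale)
        idx = np.clip(raw.astype(np.int64), 0, len(self._sf))
        sf = np.append(self._sf, 0.0)  # len(sf) -> p = 0 sentinel
        out = sf[idx]
        out[~finite] = 1.0
        return out

    def score_threshold(self, p_threshold: float) -> float:
        """Smallest representable score whose p-value is < ``p_threshold``."""
        idx = int(np.searchsorted(-self._sf, -p_threshold, side="right"))
        return idx / self._scale + self._offset


def score_distribution(
    pwm: PositionWeightMatrix, granularity: int = 1000
) -> ScoreDistribution:
    return ScoreDistribution(pwm, granularity)


def _window_scores(encoded: np.ndarray, llr: np.ndarray) -> np.ndarray:
    """Log-odds score of every window; windows containing N score -inf."""
    L = llr.shape[1]
    n_win = len(encoded) - L + 1
    if n_win <= 0:
        return np.empty(0)
    windows = np.lib.stride_tricks.sliding_window_view(encoded, L)
    valid = (windows >= 0).all(axis=1)
    safe = np.where(windows >= 0, windows, 0)
    scores = llr[safe, np.arange(L)].sum(axis=1)
    scores[~valid] = -np.inf
    return scores


def scan_sequence(
    seq: str,
    pwm: PositionWeightMatrix,
    dist: ScoreDistribution,
    p_threshold: float = 1e-4,
    chrom: str = ".",
    offset: int = 0,
    source_peak: str = ".",
) -> list[MotifHit]:
    """Score every window of ``seq`` on both strands; keep hits with
    p-value < ``p_threshold``.  Minus-strand hits are reported on the
    plus strand's coordinates."""
    encoded = encode_sequence(seq)
    L = pwm.length
    hits: list[MotifHit] = []
    rc_llr = pwm.reverse_complement().log_likelihood_ratios
    for strand, llr in (("+", pwm.log_likelihood_ratios), ("-", rc_llr)):
        scores = _window_scores(encoded, llr)
        if scores.size == 0:
            continue
        pvals = dist.p_values(scores)
        for w in np.flatnonzero(pvals < p_threshold):
            hits.append(
                MotifHit(
                    chrom=chrom,
                    start=offset + int(w),
                    end=offset + int(w) + L,
                    strand=strand,
                    score=float(scores[w]),
                    p_value=float(pvals[w]),
                    tf_name=pwm.tf_name,
                    source_peak=source_peak,
                )
            )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def scan_peaks(
    genome: Mapping[str, str],
    peaks: Sequence,
    pwm: PositionWeightMatrix,
    p_threshold: float = 1e-4,
    granularity: int = 1000,
) -> list[MotifHit]:
    """Scan the sequence inside each peak interval for PWM hits."""
    dist = ScoreDistribution(pwm, granularity)
    hits: list[MotifHit] = []
    for i, peak in enumerate(peaks):
        if peak.chrom not in genome:
            raise KeyError(f"chromosome {peak.chrom} absent from genome")
        seq = genome[peak.chrom][peak.start : peak.end]
        hits.extend(
            scan_sequence(
                seq,
                pwm,
                dist,
                p_threshold,
                chrom=peak.chrom,
                offset=peak.start,
                source_peak=getattr(peak, "name", f"peak{i}"),
            )
        )
    return hits


def merge_tf_hits(hit_lists: Iterable[Sequence[MotifHit]]) -> list[MotifHit]:
    """Union of hits from several peak files of the same TF: hits that
    agree in (chrom, start, end, strand) appear once."""
    seen: dict[tuple, MotifHit] = {}
    tf_names: set[str] = set()
    for hits in hit_lists:
        for hit in hits:
            tf_names.add(hit.tf_name)
            if len(tf_names) > 1:
                raise ValueError(
                    f"cannot merge hits of different TFs: {sorted(tf_names)}"
                )
            seen.setdefault((hit.chrom, hit.start, hit.end, hit.strand), hit)
    return sorted(
        seen.values(), key=lambda h: (h.chrom, h.start, h.end, h.strand)
    )


def assign_hits_to_dyads(
    hits: Sequence[MotifHit], dyads: Sequence
) -> list[AssignedHit]:
    """Map each hit to the closest representative dyad on its chromosome.

    Distance is from the hit's center base (left-of-center for even
    lengths); equidistant dyads resolve to the lower coordinate.  Hits on
    chromosomes without dyads are left unassigned (and logged).
    """
    by_chrom: dict[str, np.ndarray] = {}
    for d in dyads:
        by_chrom.setdefault(d.chrom, []).append(d.position)  # type: ignore
    by_chrom = {c: np.sort(np.asarray(p)) for c, p in by_chrom.items()}
    assigned: list[AssignedHit] = []
    n_unassigned = 0
    for hit in hits:
        positions = by_chrom.get(hit.chrom)
        if positions is None or positions.size == 0:
            n_unassigned += 1
            continue
        center = hit.center()
        idx = int(np.searchsorted(positions, center))
        best = None
        for j in (idx - 1, idx):
            if 0 <= j < positions.size:
                cand = int(positions[j])
                key = (abs(center - cand), cand)
                if best is None or key < best[0]:
                    best = (key, cand)
        dyad_pos = best[1]  # type: ignore[index]
        assigned.append(AssignedHit(hit, dyad_pos, center - dyad_pos))
    if n_unassigned:
        logger.info("%d hits on chromosomes without dyads", n_unassigned)
    return assigned
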