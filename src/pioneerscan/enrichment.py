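"""Motif enrichment of TFs on nucleosome regions versus depleted regions.

For each TF a 2x2 contingency table is built from base-pair counts:
``a``/``c`` are the bases of the TF's motif hits covered by the NR and
NDR unions, ``b``/``d`` the remaining NR and NDR bases.  The enrichment
score is the odds ratio ``(a/c) / (b/d)``; pioneer transcription
factors, which tolerate or prefer nucleosomal DNA, score above 1 while
canonical factors confined to open, nucleosome-free DNA score below 1.
Significance comes from Fisher's exact test with Benjamini-Hochberg FDR
across TFs, and classifier quality of the score ranking is evaluated by
ROC AUC, PR AUC and the maximal Matthews correlation coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score
from statsmodels.stats.multitest import multipletests

from .intervals import covered_length, merge_intervals
from .io import ExpressionTable
from .scan import MotifHit

__all__ = [
    "ContingencyTable",
    "EnrichmentResult",
    "ClassificationMetrics",
    "build_contingency",
    "enrichment_score",
    "fisher_exact",
    "bh_fdr",
    "score_tf",
    "rank_tfs",
    "evaluate_classifier",
    "mannwhitney_group_test",
]


@dataclass(frozen=True)
class ContingencyTable:
    """Motif / non-motif base pairs on NRs (a, b) and NDRs (c, d)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def nr_total(self) -> int:
        return self.a + self.b

    @property
    def ndr_total(self) -> int:
        return self.c + self.d


@dataclass
class EnrichmentResult:
    tf_name: str
    table: ContingencyTable
    enrichment_score: float
    fisher_p: float
    fdr_q: float = 1.0
    cell_line: str = ""
    rpkm: float | None = None
    highly_expressed: bool | None = None  # None = expression unknown
    corrected: bool = False  # continuity correction applied


@dataclass(frozen=True)
class ClassificationMetrics:
    roc_auc: float
    pr_auc: float
    mcc_max: float
    threshold_at_mcc_max: float


def build_contingency(
    hits: Sequence[MotifHit],
    nr_regions: Sequence,
    ndr_regions: Sequence,
) -> ContingencyTable:
    """Count motif base pairs on the NR and NDR unions.

    Motif intervals are unioned first so a base covered by overlapping
    hits counts once; region sets are likewise merged internally.
    """
    if not nr_regions or not ndr_regions:
        raise ValueError("need non-empty NR and NDR sets")
    hits_by_chrom: dict[str, list] = {}
    for h in hits:
        hits_by_chrom.setdefault(h.chrom, []).append(h)
    merged_hits = {
        c: merge_intervals(hs) for c, hs in hits_by_chrom.items()
    }

    def count(regions: Sequence) -> tuple[int, int]:
        by_chrom: dict[str, list] = {}
        for r in regions:
            by_chrom.setdefault(r.chrom, []).append(r)
        motif_bp = 0
        total_bp = 0
        for chrom, regs in by_chrom.items():
            merged_regs = merge_intervals(regs)
            total_bp += sum(e - s for s, e in merged_regs)
            motif_bp += covered_length(
                merged_regs, merged_hits.get(chrom, [])
            )
        return motif_bp, total_bp

    a, nr_total = count(nr_regions)
    c, ndr_total = count(ndr_regions)
    return ContingencyTable(a, nr_total - a, c, ndr_total - c)


def enrichment_score(table: ContingencyTable) -> tuple[float, bool]:
    """Odds ratio ``(a/c) / (b/d)``.

    A zero in any cell triggers the Haldane-Anscombe correction (+0.5 to
    all four cells); the returned flag records whether it was applied.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    corrected = 0 in (a, b, c, d)
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a / c) / (b / d), corrected


def fisher_exact(table: ContingencyTable) -> float:
    """Two-sided Fisher exact p: total probability of tables (at the
    observed margins) no more likely than the observed one."""
    _, p = stats.fisher_exact(
        [[table.a, table.b], [table.c, table.d]], alternative="two-sided"
    )
    # large unbalanced tables underflow to 0; keep p in (0, 1]
    return max(float(p), np.finfo(float).tiny)


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (order-preserving, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def score_tf(
    tf_name: str,
    hits: Sequence[MotifHit],
    nr_regions: Sequence,
    ndr_regions: Sequence,
    cell_line: str = "",
) -> EnrichmentResult:
    """Contingency table, odds ratio and Fisher p for one TF."""
    table = build_contingency(hits, nr_regions, ndr_regions)
    score, corrected = enrichment_score(table)
    return EnrichmentResult(
        tf_name=tf_name,
        table=table,
        enrichment_score=score,
        fisher_p=fisher_exact(table),
        cell_line=cell_line,
        corrected=corrected,
    )


def rank_tfs(
    results: Sequence[EnrichmentResult],
    expression: ExpressionTable | None = None,
    rpkm_min: float = 10.0,
) -> list[EnrichmentResult]:
    """Attach FDR q-values and expression flags; sort by descending
    enrichment score (score ties broken by TF name for determinism).

    ``highly_expressed`` is True at RPKM >= ``rpkm_min``, False below,
    and None for TFs absent from the expression table.
    """
    results = list(results)
    if results:
        qs = bh_fdr([r.fisher_p for r in results])
        for r, q in zip(results, qs):
            r.fdr_q = float(q)
    if expression is not None:
        for r in results:
            rpkm = expression.get(r.tf_name)
            r.rpkm = rpkm
            r.highly_expressed = None if rpkm is None else rpkm >= rpkm_min
    return sorted(results, key=lambda r: (-r.enrichment_score, r.tf_name))


def _max_mcc(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Matthews correlation coefficient maximized over all thresholds of
    the rule 'predict positive when score >= t'."""
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order].astype(float)
    P = y.sum()
    N = len(y) - P
    tp = np.cumsum(y)
    fp = np.cumsum(1 - y)
    # evaluate only at distinct-score boundaries
    last_of_tie = np.append(s[1:] != s[:-1], True)
    best_mcc, best_thr = -1.0, float(s[0])
    for i in np.flatnonzero(last_of_tie):
        tp_i, fp_i = tp[i], fp[i]
        fn_i, tn_i = P - tp_i, N - fp_i
        denom = np.sqrt(
            (tp_i + fp_i) * (tp_i + fn_i) * (tn_i + fp_i) * (tn_i + fn_i)
        )
        mcc = 0.0 if denom == 0 else (tp_i * tn_i - fp_i * fn_i) / denom
        if mcc > best_mcc:
            best_mcc, best_thr = float(mcc), float(s[i])
    return best_mcc, best_thr


def evaluate_classifier(
    scores: Mapping[str, float], labels: Mapping[str, bool]
) -> ClassificationMetrics:
    """ROC AUC, PR AUC and maximal MCC of a score ranking vs binary labels.

    ROC AUC uses the rank (Mann-Whitney) formulation with ties averaged;
    PR AUC is the step-wise interpolated average precision.  Only TFs
    present in both mappings are evaluated.
    """
    common = sorted(set(scores) & set(labels))
    s = np.array([scores[t] for t in common], dtype=float)
    y = np.array([bool(labels[t]) for t in common])
    if y.all() or not y.any():
        raise ValueError("need at least one positive and one negative label")
    mcc, thr = _max_mcc(s, y)
    return ClassificationMetrics(
        roc_auc=float(roc_auc_score(y, s)),
        pr_auc=float(average_precision_score(y, s)),
        mcc_max=mcc,
        threshold_at_mcc_max=thr,
    )


def mannwhitney_group_test(
    scores_a: Sequence[float], scores_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U comparing enrichment scores of two TF
    groups (e.g. known pioneer factors vs the rest)."""
    u, p = stats.mannwhitneyu(scores_a, scores_b, alternative="two-sided")
    return float(u), float(p)
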