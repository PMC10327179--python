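"""Contingency counting, odds ratio, Fisher test vs hypergeometric
enumeration, BH FDR, ranking and classifier metrics."""

from math import comb

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pioneerscan.enrichment import (
    ContingencyTable,
    bh_fdr,
    build_contingency,
    enrichment_score,
    evaluate_classifier,
    fisher_exact,
    mannwhitney_group_test,
    rank_tfs,
    score_tf,
)
from pioneerscan.intervals import GenomicInterval
from pioneerscan.io import ExpressionTable
from pioneerscan.scan import MotifHit


def hit(start, end, chrom="chr1"):
    return MotifHit(chrom, start, end, "+", 1.0, 1e-5, "T")


def enumerate_fisher(a, b, c, d):
    """Exhaustive two-sided Fisher p at fixed margins: sum the
    hypergeometric probabilities of every table no more likely than the
    observed one."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x):  # table (x, r1-x, c1-x, r2-c1+x)
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    lo, hi = max(0, c1 - r2), min(r1, c1)
    p_obs = prob(a)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-12))


class TestContingency:
    NR = [GenomicInterval("chr1", 1000, 1147)]
    NDR = [GenomicInterval("chr1", 5000, 6000)]

    def test_motif_inside_nr(self):
        t = build_contingency([hit(1050, 1060)], self.NR, self.NDR)
        assert (t.a, t.b, t.c, t.d) == (10, 137, 0, 1000)

    def test_motif_straddling_nr_boundary(self):
        t = build_contingency([hit(996, 1004)], self.NR, self.NDR)
        assert t.a == 4

    def test_overlapping_hits_count_union(self):
        t = build_contingency(
            [hit(1050, 1060), hit(1055, 1065)], self.NR, self.NDR
        )
        assert t.a == 15  # union [1050, 1065)

    def test_margins_are_region_totals(self):
        t = build_contingency([hit(1050, 1060), hit(5500, 5510)],
                              self.NR, self.NDR)
        assert t.nr_total == 147 and t.ndr_total == 1000

    def test_empty_region_set_rejected(self):
        with pytest.raises(ValueError):
            build_contingency([hit(0, 5)], [], self.NDR)


class TestEnrichmentScore:
    def test_symmetric_table(self):
        score, corrected = enrichment_score(ContingencyTable(5, 5, 5, 5))
        assert score == 1.0 and not corrected

    def test_direct_arithmetic(self):
        score, _ = enrichment_score(ContingencyTable(30, 970, 10, 990))
        assert score == pytest.approx((30 / 10) / (970 / 990))
        assert score == pytest.approx(3.06186, abs=1e-5)

    def test_zero_cell_haldane_anscombe(self):
        score, corrected = enrichment_score(ContingencyTable(10, 90, 0, 100))
        assert corrected
        assert score == pytest.approx((10.5 / 0.5) / (90.5 / 100.5))

    @settings(max_examples=50, deadline=None)
    @given(st.tuples(*[st.integers(1, 500)] * 4))
    def test_reciprocal_identity(self, cells):
        a, b, c, d = cells
        s1, _ = enrichment_score(ContingencyTable(a, b, c, d))
        s2, _ = enrichment_score(ContingencyTable(c, d, a, b))
        assert s1 * s2 == pytest.approx(1.0)


class TestFisher:
    def test_balanced_table(self):
        assert fisher_exact(ContingencyTable(5, 5, 5, 5)) == 1.0

    def test_small_table_exact_fraction(self):
        assert fisher_exact(ContingencyTable(3, 1, 1, 3)) == pytest.approx(
            34 / 70
        )

    @settings(max_examples=40, deadline=None)
    @given(st.tuples(*[st.integers(0, 20)] * 4))
    def test_matches_enumeration_for_small_margins(self, cells):
        a, b, c, d = cells
        if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
            return
        p = fisher_exact(ContingencyTable(a, b, c, d))
        assert p == pytest.approx(enumerate_fisher(a, b, c, d), abs=1e-9)

    def test_transpose_invariance(self):
        t = ContingencyTable(12, 3, 7, 18)
        tt = ContingencyTable(12, 7, 3, 18)
        assert fisher_exact(t) == pytest.approx(fisher_exact(tt), rel=1e-12)


class TestBhFdr:
    def test_step_up_rule_by_hand(self):
        # q3 = 0.03; q2 = min(0.03, 3*0.02/2)=0.03; q1 = min(0.03, 3*0.01)=0.03
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03] * 3)

    def test_single_p(self):
        assert bh_fdr([0.2])[0] == pytest.approx(0.2)

    def test_all_ones(self):
        np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_rejects_zero(self):
        with pytest.raises(ValueError):
            bh_fdr([0.0, 0.5])


class TestRanking:
    def _result(self, tf, score, p=0.01):
        return score_tf(
            tf,
            [hit(1050, 1050 + max(int(score * 10), 1))],
            [GenomicInterval("chr1", 1000, 1147)],
            [GenomicInterval("chr1", 5000, 6000)],
        )

    def test_descending_order_and_expression_flags(self):
        results = [self._result("A", 2.0), self._result("B", 5.0),
                   self._result("C", 1.0)]
        expr = ExpressionTable("K562", {"A": 10.0, "B": 3.0})
        ranked = rank_tfs(results, expr)
        names = [r.tf_name for r in ranked]
        assert names == sorted(
            names, key=lambda n: -next(
                r.enrichment_score for r in ranked if r.tf_name == n
            )
        )
        flags = {r.tf_name: r.highly_expressed for r in ranked}
        assert flags == {"A": True, "B": False, "C": None}  # RPKM 10 is high

    def test_tied_scores_ordered_by_name(self):
        r1 = self._result("ZZZ", 2.0)
        r2 = self._result("AAA", 2.0)
        ranked = rank_tfs([r1, r2])
        assert [r.tf_name for r in ranked] == ["AAA", "ZZZ"]

    def test_qvalues_attached(self):
        ranked = rank_tfs([self._result("A", 2.0), self._result("B", 1.0)])
        assert all(0 < r.fdr_q <= 1 for r in ranked)


class TestClassifierMetrics:
    def test_perfect_separation(self):
        m = evaluate_classifier(
            {"a": 0.9, "b": 0.8, "c": 0.1},
            {"a": True, "b": True, "c": False},
        )
        assert m.roc_auc == 1.0 and m.mcc_max == pytest.approx(1.0)
        assert m.pr_auc == 1.0

    def test_auc_by_concordant_pair_count(self):
        # labels (1,0,1,0) on descending scores: 3 of 4 pos/neg pairs concordant
        m = evaluate_classifier(
            {"a": 0.8, "b": 0.6, "c": 0.4, "d": 0.2},
            {"a": True, "b": False, "c": True, "d": False},
        )
        assert m.roc_auc == pytest.approx(0.75)

    def test_label_swap_flips_auc(self):
        rng = np.random.default_rng(0)
        scores = {f"t{i}": float(s) for i, s in enumerate(rng.normal(size=40))}
        labels = {t: bool(i % 3 == 0) for i, t in enumerate(scores)}
        m1 = evaluate_classifier(scores, labels)
        m2 = evaluate_classifier(scores, {t: not v for t, v in labels.items()})
        assert m1.roc_auc == pytest.approx(1 - m2.roc_auc)

    def test_mcc_max_against_direct_threshold_sweep(self):
        rng = np.random.default_rng(1)
        scores = {f"t{i}": float(s) for i, s in enumerate(rng.normal(size=30))}
        labels = {t: bool(rng.random() < 0.4) for t in scores}
        if not any(labels.values()) or all(labels.values()):
            labels["t0"] = True
            labels["t1"] = False
        m = evaluate_classifier(scores, labels)
        best = -1.0
        y = np.array([labels[t] for t in scores])
        s = np.array([scores[t] for t in scores])
        for thr in np.unique(s):
            pred = s >= thr
            tp = (pred & y).sum(); fp = (pred & ~y).sum()
            fn = (~pred & y).sum(); tn = (~pred & ~y).sum()
            denom = np.sqrt(float((tp+fp)*(tp+fn)*(tn+fp)*(tn+fn)))
            mcc = 0.0 if denom == 0 else (tp*tn - fp*fn)/denom
            best = max(best, mcc)
        assert m.mcc_max == pytest.approx(best)

    def test_degenerate_labels_rejected(self):
        with pytest.raises(ValueError):
            evaluate_classifier({"a": 1.0, "b": 0.5}, {"a": True, "b": True})


class TestSyntheticEnrichmentDirection:
    """Motifs implanted only in NRs score > 1; only in NDRs score < 1."""

    NR = [GenomicInterval("chr1", i * 1000, i * 1000 + 147) for i in range(20)]
    NDR = [GenomicInterval("chr1", i * 1000 + 500, i * 1000 + 800)
           for i in range(20)]

    def test_nr_implants_enriched(self):
        hits = [hit(i * 1000 + 50, i * 1000 + 60) for i in range(20)]
        r = score_tf("T", hits, self.NR, self.NDR)
        assert r.enrichment_score > 1
        assert r.fisher_p < 0.05

    def test_ndr_implants_depleted(self):
        hits = [hit(i * 1000 + 600, i * 1000 + 610) for i in range(20)]
        r = score_tf("T", hits, self.NR, self.NDR)
        assert r.enrichment_score < 1
        assert r.fisher_p < 0.05


def test_mannwhitney_direction():
    u, p = mannwhitney_group_test([5.0, 6.0, 7.0], [1.0, 1.5, 2.0])
    assert p < 0.2
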