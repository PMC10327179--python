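"""PWM construction, exact p-values vs enumeration, scanning vs a
brute-force window scorer, strand symmetry and dyad assignment."""

import itertools

import numpy as np
import pytest

from pioneerscan.dyads import RepresentativeDyad
from pioneerscan.io import PositionFrequencyMatrix
from pioneerscan.scan import (
    MotifHit,
    ScoreDistribution,
    assign_hits_to_dyads,
    encode_sequence,
    merge_tf_hits,
    pfm_to_pwm,
    scan_peaks,
    scan_sequence,
)
from pioneerscan.simulate import make_pfm, revcomp


def random_pfm(rng, L):
    counts = rng.integers(0, 20, size=(4, L)) + rng.integers(0, 2, size=(4, L))
    counts[rng.integers(0, 4), :] += 1  # guarantee positive column sums
    return PositionFrequencyMatrix("RND", counts.astype(float))


def brute_force_pvalues(pwm, granularity=1000):
    """Enumerate all 4^L words in the integer-discretized score domain.

    Independent re-derivation of the null distribution: discretize each
    column exactly as stated (shift by the column minimum, scale so the
    largest column range maps to ``granularity``, round to nearest), then
    sum word probabilities under the background.
    """
    llr = pwm.log_likelihood_ratios
    L = llr.shape[1]
    col_min = llr.min(axis=0)
    max_range = (llr.max(axis=0) - col_min).max()
    scale = granularity / max_range if max_range > 0 else 1.0
    int_scores = np.rint((llr - col_min) * scale).astype(int)
    word_probs = {}
    for word in itertools.product(range(4), repeat=L):
        s = sum(int_scores[b, k] for k, b in enumerate(word))
        p = np.prod([pwm.background[b] for b in word])
        word_probs[s] = word_probs.get(s, 0.0) + p
    return int_scores, col_min, scale, word_probs


class TestPfmToPwm:
    def test_uniform_column_scores_zero(self):
        pfm = PositionFrequencyMatrix("U", np.ones((4, 3)))
        pwm = pfm_to_pwm(pfm)
        np.testing.assert_allclose(pwm.log_likelihood_ratios, 0, atol=1e-12)

    def test_pure_column_small_pseudocount_limit(self):
        pfm = PositionFrequencyMatrix("P", np.array([[10.0], [0], [0], [0]]))
        pwm = pfm_to_pwm(pfm, pseudocount=1e-9)
        # as the pseudocount vanishes, the consensus entry -> log2(1/0.25)
        assert pwm.log_likelihood_ratios[0, 0] == pytest.approx(2.0, abs=1e-9)

    def test_matches_hand_computation(self):
        # column (A:3, C:1, G:0, T:0), pseudocount 0.1, uniform background
        pfm = PositionFrequencyMatrix(
            "H", np.array([[3.0], [1.0], [0.0], [0.0]])
        )
        pwm = pfm_to_pwm(pfm, pseudocount=0.1)
        expected = np.log2(
            ((np.array([3, 1, 0, 0]) + 0.1 * 0.25) / (4 + 0.1)) / 0.25
        )
        np.testing.assert_allclose(
            pwm.log_likelihood_ratios[:, 0], expected, rtol=1e-12
        )


class TestScoreDistribution:
    def test_single_position_best_base(self):
        pfm = PositionFrequencyMatrix(
            "L1", np.array([[8.0], [4.0], [2.0], [1.0]])
        )
        pwm = pfm_to_pwm(pfm)
        dist = ScoreDistribution(pwm)
        assert dist.p_value(pwm.max_score()) == pytest.approx(0.25)

    def test_dinucleotide_unique_argmax(self):
        pfm = PositionFrequencyMatrix(
            "L2", np.array([[8.0, 1.0], [4, 8], [2, 4], [1, 2]])
        )
        pwm = pfm_to_pwm(pfm)
        assert ScoreDistribution(pwm).p_value(pwm.max_score()) == pytest.approx(
            1 / 16
        )

    def test_threshold_below_minimum_gives_one(self):
        pwm = pfm_to_pwm(
            PositionFrequencyMatrix("L", np.array([[8.0], [4], [2], [1]]))
        )
        assert ScoreDistribution(pwm).p_value(-100.0) == 1.0

    @pytest.mark.parametrize("L,seed", [(2, 0), (4, 1), (6, 2), (8, 3)])
    def test_matches_exhaustive_enumeration(self, L, seed):
        """DP survival function equals 4^L enumeration at the
        discretization resolution, for every attainable word score."""
        rng = np.random.default_rng(seed)
        pwm = pfm_to_pwm(random_pfm(rng, L))
        dist = ScoreDistribution(pwm)
        int_scores, col_min, scale, word_probs = brute_force_pvalues(pwm)
        totals = np.array(sorted(word_probs))
        probs = np.array([word_probs[t] for t in totals])
        sf = probs[::-1].cumsum()[::-1]
        offset = col_min.sum()
        for t, expected in zip(totals, sf):
            score = t / scale + offset
            assert dist.p_value(score) == pytest.approx(expected, rel=1e-9)

    def test_pvalue_monotone_in_score(self):
        pwm = pfm_to_pwm(random_pfm(np.random.default_rng(7), 5))
        dist = ScoreDistribution(pwm)
        grid = np.linspace(-10, pwm.max_score() + 1, 200)
        pv = [dist.p_value(s) for s in grid]
        assert all(a >= b for a, b in zip(pv, pv[1:]))


def brute_force_scan(seq, pwm, dist, p_threshold):
    """Score every window on both strands directly from the matrices."""
    L = pwm.length
    llr = pwm.log_likelihood_ratios
    out = []
    for strand in "+-":
        for w in range(len(seq) - L + 1):
            word = seq[w : w + L]
            scan_word = word if strand == "+" else revcomp(word)
            if any(b not in "ACGT" for b in scan_word):
                continue
            s = sum(
                llr["ACGT".index(b), k] for k, b in enumerate(scan_word)
            )
            if dist.p_value(s) < p_threshold:
                out.append((w, w + L, strand))
    return sorted(out)


class TestScanning:
    def test_plant_and_recover_exact_coordinates(self):
        rng = np.random.default_rng(5)
        pfm = make_pfm("T", "ATGCACGTT")
        pwm = pfm_to_pwm(pfm)
        dist = ScoreDistribution(pwm)
        seq = "".join(rng.choice(list("ACGT"), size=400))
        planted = seq[:137] + "ATGCACGTT" + seq[146:]
        hits = scan_sequence(planted, pwm, dist, 1e-4)
        consensus_hits = [h for h in hits if (h.start, h.strand) == (137, "+")]
        assert len(consensus_hits) == 1
        assert consensus_hits[0].end == 146

    def test_reverse_complement_hit_same_interval(self):
        pfm = make_pfm("T", "ATGCACGTT")
        pwm = pfm_to_pwm(pfm)
        dist = ScoreDistribution(pwm)
        pad = "C" * 50
        fwd = pad + "ATGCACGTT" + pad
        rc = pad + revcomp("ATGCACGTT") + pad
        fwd_hits = scan_sequence(fwd, pwm, dist, 1e-4)
        rc_hits = scan_sequence(rc, pwm, dist, 1e-4)
        assert [(h.start, h.end) for h in fwd_hits] == [
            (h.start, h.end) for h in rc_hits
        ]
        assert {h.strand for h in fwd_hits} == {"+"}
        assert {h.strand for h in rc_hits} == {"-"}

    @pytest.mark.parametrize("L,seed", [(4, 10), (6, 11), (8, 12)])
    def test_matches_brute_force_scanner(self, L, seed):
        rng = np.random.default_rng(seed)
        pwm = pfm_to_pwm(random_pfm(rng, L))
        dist = ScoreDistribution(pwm)
        seq = "".join(rng.choice(list("ACGTN"), size=2000,
                                 p=[0.24, 0.24, 0.24, 0.24, 0.04]))
        p_thr = 0.01
        hits = scan_sequence(seq, pwm, dist, p_thr)
        got = sorted((h.start, h.end, h.strand) for h in hits)
        assert got == brute_force_scan(seq, pwm, dist, p_thr)

    def test_n_bases_never_hit(self):
        pwm = pfm_to_pwm(make_pfm("T", "AAAA"))
        dist = ScoreDistribution(pwm)
        seq = "AANAAAAA"
        hits = scan_sequence(seq, pwm, dist, p_threshold=0.9)
        assert hits  # the N-free AAAA windows do match
        assert all("N" not in seq[h.start : h.end] for h in hits)

    def test_null_hit_rate_matches_binomial_expectation(self):
        rng = np.random.default_rng(99)
        pfm = make_pfm("T", "ATGCACGTTACG", strength=50)  # 12-bp strong PWM
        pwm = pfm_to_pwm(pfm)
        dist = ScoreDistribution(pwm)
        seq = "".join(rng.choice(list("ACGT"), size=10_000))
        p_thr = 1e-3
        hits = scan_sequence(seq, pwm, dist, p_thr)
        # attained p at the effective cutoff, not the nominal threshold
        p_att = dist.p_value(dist.score_threshold(p_thr))
        n_win = 2 * (10_000 - 12 + 1)
        expect = n_win * p_att
        sd = np.sqrt(n_win * p_att * (1 - p_att))
        assert abs(len(hits) - expect) <= 3 * sd

    def test_missing_chromosome_raises(self):
        pwm = pfm_to_pwm(make_pfm("T", "ACGT"))

        class Peak:
            chrom, start, end, name = "chrX", 0, 10, "p"

        with pytest.raises(KeyError, match="chrX"):
            scan_peaks({"chr1": "ACGT" * 10}, [Peak()], pwm)


class TestHitBookkeeping:
    def _hit(self, start, strand="+", tf="T"):
        return MotifHit("chr1", start, start + 5, strand, 1.0, 1e-5, tf)

    def test_merge_deduplicates_shared_hits(self):
        a = [self._hit(10), self._hit(20)]
        b = [self._hit(20), self._hit(30)]
        assert len(merge_tf_hits([a, b])) == 3

    def test_merge_keeps_opposite_strands(self):
        merged = merge_tf_hits([[self._hit(10, "+")], [self._hit(10, "-")]])
        assert len(merged) == 2

    def test_merge_rejects_mixed_tfs(self):
        with pytest.raises(ValueError):
            merge_tf_hits([[self._hit(10, tf="A")], [self._hit(20, tf="B")]])

    def test_assignment_to_closest_dyad(self):
        dyads = [
            RepresentativeDyad("chr1", 1073, 1, 1073),
            RepresentativeDyad("chr1", 1300, 1, 1300),
        ]
        hit = MotifHit("chr1", 1076, 1086, "+", 1.0, 1e-5, "T")  # center 1080
        (a,) = assign_hits_to_dyads([hit], dyads)
        assert a.dyad_position == 1073
        assert a.center_offset == 7

    def test_equidistant_tie_takes_lower_dyad(self):
        dyads = [
            RepresentativeDyad("chr1", 1050, 1, 1050),
            RepresentativeDyad("chr1", 1150, 1, 1150),
        ]
        hit = MotifHit("chr1", 1098, 1103, "+", 1.0, 1e-5, "T")  # center 1100
        (a,) = assign_hits_to_dyads([hit], dyads)
        assert a.dyad_position == 1050

    def test_chromosome_without_dyads_unassigned(self):
        hit = MotifHit("chr2", 10, 15, "+", 1.0, 1e-5, "T")
        assert assign_hits_to_dyads([hit], []) == []
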