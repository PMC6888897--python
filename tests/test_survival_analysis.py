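"""Kaplan-Meier, log-rank and best-cutoff: hand values, symmetry, oracle agreement."""

import numpy as np
import pytest
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as ll_logrank

from kdsig import (
    DegenerateTestError,
    ParameterError,
    ValidationError,
    best_cutoff,
    km_estimate,
    logrank_test,
)
from _oracles import km_by_hand


class TestKaplanMeier:
    def test_two_events_no_censoring(self):
        c = km_estimate([1, 2], [1, 1])
        np.testing.assert_allclose(c.event_times, [1, 2])
        np.testing.assert_allclose(c.survival, [0.5, 0.0])

    def test_all_censored_curve_stays_at_one(self):
        c = km_estimate([1, 2, 3], [0, 0, 0])
        assert c.event_times.size == 0
        assert c.survival_at(10.0) == 1.0

    def test_censoring_reduces_risk_set_only(self):
        c = km_estimate([1, 2, 3], [1, 0, 1])
        np.testing.assert_allclose(c.event_times, [1, 3])
        np.testing.assert_allclose(c.survival, [2 / 3, 0.0])  # (1-1/3)*(1-1/1)

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            km_estimate([], [])

    def test_survival_non_increasing_and_starts_below_one(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(10, 40)
        e = rng.integers(0, 2, 40)
        e[0] = 1
        c = km_estimate(t, e)
        assert np.all(np.diff(c.survival) <= 1e-12)
        assert c.survival_at(0.0) == 1.0 if c.event_times[0] > 0 else True

    def test_merged_duplicates_equal_weighted_records(self):
        base_t, base_e = [2.0, 2.0, 2.0, 5.0, 7.0, 7.0], [1, 1, 1, 0, 1, 1]
        c1 = km_estimate(base_t, base_e)
        t2, s2 = km_by_hand(base_t, base_e)
        np.testing.assert_allclose(c1.event_times, t2)
        np.testing.assert_allclose(c1.survival, s2)


class TestLogRank:
    def test_mirrored_groups_give_null(self):
        t = [1, 2, 3, 1, 2, 3]
        e = [1, 0, 1, 1, 0, 1]
        g = ["A"] * 3 + ["B"] * 3
        res = logrank_test(t, e, g)
        assert res.chi_square == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_two_singleton_groups_hand_computation(self):
        res = logrank_test([1, 2], [1, 1], ["A", "B"])
        assert res.chi_square == pytest.approx(1.0, abs=1e-9)
        assert res.p_value == pytest.approx(0.31731050786291415, abs=1e-9)
        assert res.observed["A"] == 1.0
        assert res.expected["A"] == pytest.approx(0.5)

    def test_observed_and_expected_totals_match(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(5, 30)
        e = rng.integers(0, 2, 30)
        e[:5] = 1
        g = np.where(rng.random(30) < 0.5, "A", "B")
        res = logrank_test(t, e, g)
        assert sum(res.observed.values()) == pytest.approx(sum(res.expected.values()))

    def test_label_swap_symmetric_and_inverts_hr(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(5, 40)
        e = np.ones(40, dtype=int)
        g = np.where(rng.random(40) < 0.5, "A", "B")
        res1 = logrank_test(t, e, g)
        res2 = logrank_test(t, e, np.where(g == "A", "Z", "A"))  # A<->Z swaps order
        assert res1.chi_square == pytest.approx(res2.chi_square, abs=1e-12)
        assert res1.p_value == pytest.approx(res2.p_value, abs=1e-12)
        assert res1.hr_estimate == pytest.approx(1.0 / res2.hr_estimate, rel=1e-9)

    def test_no_events_is_degenerate(self):
        with pytest.raises(DegenerateTestError):
            logrank_test([1, 2, 3, 4], [0, 0, 0, 0], ["A", "A", "B", "B"])

    def test_agrees_with_independent_reference_on_random_data(self):
        """chi2 and S(t) match lifelines within 1e-8 on 50 random small datasets."""
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = int(rng.integers(10, 31))
            t = np.round(rng.exponential(10, n), 1) + 0.1
            e = (rng.random(n) < 0.7).astype(int)
            if e.sum() == 0:
                e[0] = 1
            g = np.where(rng.random(n) < 0.5, "A", "B")
            if len(np.unique(g)) < 2:
                g[0] = "A" if g[0] == "B" else "B"
            mine = logrank_test(t, e, g)
            ref = ll_logrank(t[g == "A"], t[g == "B"], e[g == "A"], e[g == "B"])
            assert mine.chi_square == pytest.approx(ref.test_statistic, abs=1e-8)
            assert mine.p_value == pytest.approx(ref.p_value, abs=1e-8)

            curve = km_estimate(t, e)
            kmf = KaplanMeierFitter().fit(t, e)
            ref_s = kmf.survival_function_at_times(curve.event_times).to_numpy()
            np.testing.assert_allclose(curve.survival, ref_s, atol=1e-8)


class TestBestCutoff:
    @staticmethod
    def _separated_cohort(seed=0, n=60):
        rng = np.random.default_rng(seed)
        scores = np.r_[rng.normal(-3, 0.5, n // 2), rng.normal(3, 0.5, n // 2)]
        hazard = np.where(scores < 0, 0.2, 0.02)
        t = rng.exponential(1 / hazard)
        e = np.ones(n, dtype=int)
        return scores, t, e

    def test_finds_cutoff_near_true_hazard_split(self):
        scores, t, e = self._separated_cohort()
        res = best_cutoff(scores, t, e, n_perm=200, seed=1)
        # the chosen split reassigns at most 2 samples vs the true sign split
        assert np.sum((scores <= res.cutoff) != (scores < 0)) <= 2
        assert res.p_adjusted < 0.05

    def test_too_few_samples_rejected(self):
        with pytest.raises(ParameterError):
            best_cutoff([1, 2, 3, 4, 5], [1, 2, 3, 4, 5], [1, 1, 1, 1, 1], n_perm=100)

    def test_nominal_p_never_exceeds_adjusted_p(self):
        rng = np.random.default_rng(3)
        for seed in range(5):
            scores = rng.normal(size=40)
            t = rng.exponential(10, 40)
            e = np.ones(40, dtype=int)
            res = best_cutoff(scores, t, e, n_perm=200, seed=seed)
            assert res.p_nominal <= res.p_adjusted

    def test_adjusted_p_uniform_under_null(self):
        """Adjusted p for score-independent survival is ~Uniform(0,1)."""
        from scipy import stats

        rng = np.random.default_rng(11)
        ps = []
        for seed in range(60):
            scores = rng.normal(size=50)
            t = rng.exponential(10, 50)
            e = np.ones(50, dtype=int)
            res = best_cutoff(scores, t, e, n_perm=200, seed=seed)
            ps.append(res.p_adjusted)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_determinism_under_fixed_seed(self):
        scores, t, e = self._separated_cohort(seed=5)
        a = best_cutoff(scores, t, e, n_perm=150, seed=9)
        b = best_cutoff(scores, t, e, n_perm=150, seed=9)
        assert (a.cutoff, a.p_nominal, a.p_adjusted) == (b.cutoff, b.p_nominal, b.p_adjusted)
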