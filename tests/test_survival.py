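"""Product-limit estimator, log-rank test, and cutpoint selection.

Independent oracles: hand product-limit computations, lifelines, and
exhaustive search over admissible splits.
"""

import numpy as np
import pytest
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as ll_logrank
from lifelines.statistics import multivariate_logrank_test

from tlsgrade.errors import NoCutpointError, UndefinedStatisticError, ValidationError
from tlsgrade.survival import (
    dichotomize,
    km_curve,
    logrank_k_groups,
    logrank_test,
    max_selected_cutpoint,
    stratified_analysis,
)


class TestKaplanMeier:
    def test_hand_product_limit(self):
        c = km_curve([5, 10, 15], [1, 1, 1])
        assert np.allclose(c.survival, [2 / 3, 1 / 3, 0.0])
        assert c.median == 10.0

    def test_all_censored(self):
        c = km_curve([3, 8, 12], [0, 0, 0])
        assert c.survival.size == 0
        assert c.survival_at(100) == 1.0
        assert c.median is None

    def test_single_event(self):
        c = km_curve([7], [1])
        assert c.survival_at(7) == 0.0
        assert c.median == 7.0

    def test_censored_subject_at_event_time_still_at_risk(self):
        # events before censorings at tied times: n at risk at t=5 is 3
        c = km_curve([5, 5, 5], [1, 0, 1])
        assert c.n_at_risk[0] == 3
        assert c.survival[0] == pytest.approx(1 / 3)

    def test_negative_times_rejected(self):
        with pytest.raises(ValidationError):
            km_curve([-1, 2], [1, 1])

    def test_matches_empirical_survival_without_censoring(self, rng):
        t = rng.exponential(10, 80)
        c = km_curve(t, np.ones(80, int))
        for q in (2.0, 5.0, 12.0):
            assert c.survival_at(q) == pytest.approx((t > q).mean())

    def test_matches_lifelines_with_censoring(self, rng):
        t = rng.exponential(10, 100)
        e = (rng.random(100) < 0.7).astype(int)
        c = km_curve(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        for q in (1.0, 4.0, 9.0, 20.0):
            assert c.survival_at(q) == pytest.approx(
                float(kmf.survival_function_at_times(q).iloc[0])
            )
        assert c.survival.size == 0 or np.all(np.diff(c.survival) <= 1e-12)


class TestLogrank:
    def test_hand_computed_example(self):
        res = logrank_test([1, 2], [1, 1], [3, 4], [1, 1])
        assert res.observed[0] == 2
        assert res.expected[0] == pytest.approx(0.8333, abs=1e-4)
        assert res.chi_square == pytest.approx(2.88, abs=0.01)

    def test_identical_groups(self):
        t, e = [2, 4, 6, 9], [1, 1, 0, 1]
        res = logrank_test(t, e, t, e)
        assert res.chi_square == pytest.approx(0.0, abs=1e-12)
        assert res.hazard_ratio == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)

    def test_label_swap_inverts_hr(self, rng):
        ta, tb = rng.exponential(5, 30), rng.exponential(10, 30)
        ea, eb = np.ones(30, int), np.ones(30, int)
        ab = logrank_test(ta, ea, tb, eb)
        ba = logrank_test(tb, eb, ta, ea)
        assert ab.chi_square == pytest.approx(ba.chi_square)
        assert ab.hazard_ratio == pytest.approx(1 / ba.hazard_ratio)

    def test_no_events_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            logrank_test([1, 2], [0, 0], [3, 4], [0, 0])

    def test_invariant_to_monotone_time_transform(self, rng):
        ta, tb = rng.exponential(5, 25), rng.exponential(8, 25)
        ea = (rng.random(25) < 0.8).astype(int)
        eb = (rng.random(25) < 0.8).astype(int)
        a = logrank_test(ta, ea, tb, eb)
        b = logrank_test(np.log1p(ta), ea, np.log1p(tb), eb)
        assert a.chi_square == pytest.approx(b.chi_square)

    def test_matches_lifelines(self, rng):
        for _ in range(10):
            ta, tb = rng.exponential(5, 40), rng.exponential(9, 35)
            ea = (rng.random(40) < 0.7).astype(int)
            eb = (rng.random(35) < 0.7).astype(int)
            if ea.sum() + eb.sum() == 0:
                continue
            mine = logrank_test(ta, ea, tb, eb)
            theirs = ll_logrank(ta, tb, ea, eb)
            assert mine.chi_square == pytest.approx(theirs.test_statistic, rel=1e-9)

    def test_k_group_specialises_to_two_group(self, rng):
        ta, tb = rng.exponential(5, 30), rng.exponential(9, 30)
        ea, eb = np.ones(30, int), np.ones(30, int)
        two = logrank_test(ta, ea, tb, eb)
        k = logrank_k_groups([(ta, ea), (tb, eb)])
        assert k.chi_square == pytest.approx(two.chi_square)
        assert k.df == 1

    def test_k_group_matches_lifelines(self, rng):
        groups = [rng.exponential(h, 25) for h in (4, 8, 12)]
        events = [np.ones(25, int)] * 3
        mine = logrank_k_groups(list(zip(groups, events)))
        t = np.concatenate(groups)
        g = np.repeat([0, 1, 2], 25)
        theirs = multivariate_logrank_test(t, g, np.ones(t.size, int))
        assert mine.chi_square == pytest.approx(theirs.test_statistic, rel=1e-9)


class TestCutpoint:
    def _brute_force(self, vals, t, e, minprop):
        best = None
        min_group = int(np.ceil(minprop * len(vals)))
        for c in np.unique(vals):
            hi = vals >= c
            if hi.sum() < min_group or (~hi).sum() < min_group:
                continue
            res = logrank_test(t[hi], e[hi], t[~hi], e[~hi])
            z = np.sqrt(res.chi_square)
            if best is None or z > best[1] + 1e-9:
                best = (c, z)
        return best

    def test_equals_exhaustive_search_small_n(self, rng):
        for _ in range(25):
            vals = rng.normal(size=15)
            t = rng.exponential(5, 15)
            e = (rng.random(15) < 0.85).astype(int)
            if e.sum() == 0:
                continue
            cp = max_selected_cutpoint(vals, t, e, minprop=0.15, n_permutations=0)
            cutoff, stat = self._brute_force(vals, t, e, 0.15)
            assert cp.cutoff == pytest.approx(cutoff)
            assert cp.statistic == pytest.approx(stat, abs=1e-9)

    def test_minprop_respected(self, rng):
        vals = rng.normal(size=40)
        t = rng.exponential(5, 40)
        e = np.ones(40, int)
        cp = max_selected_cutpoint(vals, t, e, minprop=0.25, n_permutations=0)
        assert (vals >= cp.cutoff).sum() >= 10
        assert (vals < cp.cutoff).sum() >= 10

    def test_constant_feature_rejected(self):
        with pytest.raises(NoCutpointError):
            max_selected_cutpoint([1.0] * 20, range(1, 21), [1] * 20, n_permutations=0)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(NoCutpointError):
            max_selected_cutpoint([1, 2, 3], [1, 2, 3], [1, 1, 1], n_permutations=0)

    def test_permutation_p_seeded_and_unassociated_feature_nonsignificant(self, rng):
        t = rng.exponential(5, 60)
        e = np.ones(60, int)
        vals = rng.normal(size=60)  # independent of survival
        a = max_selected_cutpoint(vals, t, e, n_permutations=200, random_state=9)
        b = max_selected_cutpoint(vals, t, e, n_permutations=200, random_state=9)
        assert a.p_value == b.p_value

    def test_permutation_p_detects_planted_split(self, rng):
        vals = rng.normal(size=100)
        thr = np.quantile(vals, 0.5)
        h = np.where(vals >= thr, 0.02, 0.2)
        t = rng.exponential(1 / h)
        e = np.ones(100, int)
        cp = max_selected_cutpoint(vals, t, e, n_permutations=200, random_state=1)
        assert cp.p_value < 0.05

    def test_permutation_type_I_near_nominal(self):
        """Null features: permutation p rejects at about the nominal rate."""
        rng = np.random.default_rng(31)
        rej = 0
        n_sims = 120
        for _ in range(n_sims):
            t = rng.exponential(5, 40)
            e = np.ones(40, int)
            vals = rng.normal(size=40)
            cp = max_selected_cutpoint(vals, t, e, n_permutations=99, random_state=rng)
            if cp.p_value <= 0.05:
                rej += 1
        assert 0.005 <= rej / n_sims <= 0.11


class TestDichotomize:
    def test_threshold_convention(self):
        assert dichotomize([1, 2, 3], 2).tolist() == ["low", "high", "high"]

    def test_extreme_cutoffs(self):
        assert dichotomize([1, 2, 3], 0).tolist() == ["high"] * 3
        assert dichotomize([1, 2, 3], 99).tolist() == ["low"] * 3

    def test_nan_excluded_not_imputed(self):
        out = dichotomize([1.0, np.nan, 3.0], 2.0)
        assert out[1] is None
        assert out[0] == "low" and out[2] == "high"

    def test_nonfinite_cutoff_rejected(self):
        with pytest.raises(ValidationError):
            dichotomize([1, 2], np.nan)


class TestStratified:
    def test_identical_strata_p_one(self):
        t = [2, 4, 6, 8, 10, 12]
        e = [1, 1, 0, 1, 1, 0]
        labels = ["a", "b"] * 3
        # interleave identical outcome pairs so both strata share the data
        res = stratified_analysis(t + t, e + e, ["a"] * 6 + ["b"] * 6)
        assert res["pairwise"][0]["p_value"] == pytest.approx(1.0)

    def test_small_stratum_flagged_and_excluded(self, rng):
        t = rng.exponential(5, 21)
        e = np.ones(21, int)
        labels = ["big"] * 20 + ["tiny"]
        res = stratified_analysis(t, e, labels)
        assert res["excluded"] == ["tiny"]
        assert "tiny" not in res["strata"]

    def test_collapsing_matches_manual_subsetting(self, rng):
        """Composition: pooled grade-1+2 stratum equals manual subsetting."""
        t = rng.exponential(6, 60)
        e = (rng.random(60) < 0.8).astype(int)
        grade = rng.choice([1, 2, 3], size=60)
        labels = np.where(grade == 3, "grade3", "grade1+2")
        res = stratified_analysis(t, e, labels)
        pair = res["pairwise"][0]
        m3 = grade == 3
        manual = logrank_test(t[~m3], e[~m3], t[m3], e[m3])
        assert pair["chi_square"] == pytest.approx(manual.chi_square)
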