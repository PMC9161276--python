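"""Wilcoxon signed-rank, Kruskal-Wallis, chi-square and Fisher exact tests
against enumeration oracles and scipy cross-checks."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from tlsgrade.errors import UndefinedStatisticError, ValidationError
from tlsgrade.group_stats import (
    chi_square_test,
    choose_association_test,
    fisher_exact,
    kruskal_wallis,
    wilcoxon_signed_rank,
)


def wilcoxon_enumeration_oracle(d):
    """Exact two-sided p by enumerating all 2^n sign assignments."""
    d = np.asarray(d, float)
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    w_obs = min(ranks[d > 0].sum(), ranks[d < 0].sum())
    n = d.size
    count_le = 0
    for signs in itertools.product([0, 1], repeat=n):
        w_plus = sum(r for r, s in zip(ranks, signs) if s)
        if w_plus <= w_obs + 1e-9:
            count_le += 1
    return min(1.0, 2.0 * count_le / 2**n)


class TestWilcoxon:
    def test_five_concordant_pairs(self):
        res = wilcoxon_signed_rank([1, 2, 3, 4, 5], [0, 0, 0, 0, 0])
        assert res.statistic == 0
        assert res.p_value == pytest.approx(0.0625)
        assert res.method == "exact"

    def test_all_zero_differences_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])

    def test_zero_differences_dropped(self):
        a = wilcoxon_signed_rank([1, 2, 3, 4, 5, 7], [1, 0, 0, 0, 0, 0])
        b = wilcoxon_signed_rank([2, 3, 4, 5, 7], [0, 0, 0, 0, 0])
        assert a.n_used == 5
        assert a.p_value == pytest.approx(b.p_value)

    def test_exact_p_equals_enumeration_oracle(self, rng):
        for _ in range(10):
            x = rng.normal(size=12)
            y = rng.normal(size=12)
            res = wilcoxon_signed_rank(x, y)
            assert res.method == "exact"
            assert res.p_value == pytest.approx(wilcoxon_enumeration_oracle(x - y))

    def test_exact_p_with_ties_equals_enumeration(self, rng):
        d = rng.integers(-3, 4, size=10).astype(float)
        d[d == 0] = 1.0  # keep the sample full-size
        res = wilcoxon_signed_rank(d)
        assert res.p_value == pytest.approx(wilcoxon_enumeration_oracle(d))

    def test_exact_matches_scipy(self, rng):
        x = rng.normal(size=14)
        mine = wilcoxon_signed_rank(x)
        theirs = stats.wilcoxon(x, method="exact")
        assert mine.p_value == pytest.approx(theirs.pvalue)

    def test_normal_approximation_close_to_scipy(self, rng):
        x = rng.normal(0.3, 1.0, size=40)
        mine = wilcoxon_signed_rank(x)
        assert mine.method == "normal"
        theirs = stats.wilcoxon(x, method="approx", correction=True)
        assert mine.p_value == pytest.approx(theirs.pvalue, rel=1e-6)


class TestKruskalWallis:
    def test_direct_rank_formula_value(self):
        res = kruskal_wallis([[1, 2], [3, 4], [5, 6]])
        assert res.statistic == pytest.approx(4.571, abs=5e-4)
        assert res.df == 2

    def test_identical_groups_h_zero(self):
        res = kruskal_wallis([[1, 2, 3], [1, 2, 3]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_two_groups_equals_squared_rank_sum_statistic(self, rng):
        """Mann-Whitney equivalence at k=2 (numerical identity check)."""
        a, b = rng.normal(size=12), rng.normal(1, 1, size=15)
        res = kruskal_wallis([a, b])
        pooled = np.concatenate([a, b])
        ranks = stats.rankdata(pooled)
        n, n1 = pooled.size, a.size
        r1 = ranks[:n1].sum()
        mu = n1 * (n + 1) / 2
        var = n1 * (n - n1) * (n + 1) / 12
        assert res.statistic == pytest.approx((r1 - mu) ** 2 / var)

    def test_matches_scipy_with_ties(self, rng):
        groups = [rng.integers(0, 5, size=9).astype(float) for _ in range(3)]
        mine = kruskal_wallis(groups)
        theirs = stats.kruskal(*groups)
        assert mine.statistic == pytest.approx(theirs.statistic)
        assert mine.p_value == pytest.approx(theirs.pvalue)

    def test_single_group_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            kruskal_wallis([[1, 2, 3], []])


class TestChiSquare:
    def test_independence(self):
        res = chi_square_test([[5, 5], [5, 5]])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_perfect_association_hand_value(self):
        res = chi_square_test([[10, 0], [0, 10]])
        assert res.statistic == pytest.approx(20.0)
        assert res.df == 1
        assert np.allclose(res.expected, 5.0)

    def test_permutation_invariance(self, rng):
        table = rng.integers(1, 30, size=(3, 4))
        base = chi_square_test(table).statistic
        assert chi_square_test(table[::-1]).statistic == pytest.approx(base)
        assert chi_square_test(table[:, ::-1]).statistic == pytest.approx(base)

    def test_zero_margin_named(self):
        with pytest.raises(ValidationError, match="row"):
            chi_square_test([[0, 0], [3, 4]])
        with pytest.raises(ValidationError, match="column"):
            chi_square_test([[0, 3], [0, 4]])

    def test_matches_scipy(self, rng):
        table = rng.integers(1, 40, size=(2, 3))
        mine = chi_square_test(table)
        chi2, p, df, exp = stats.chi2_contingency(table, correction=False)
        assert mine.statistic == pytest.approx(chi2)
        assert mine.p_value == pytest.approx(p)
        assert np.allclose(mine.expected, exp)

    def test_pvalues_uniform_under_independence(self):
        """KS check of the chi-square p distribution under the null."""
        rng = np.random.default_rng(5)
        pvals = []
        for _ in range(1000):
            row = rng.multinomial(120, [0.25] * 4).reshape(2, 2)
            # resample until margins are positive (tiny chance otherwise)
            if (row.sum(0) == 0).any() or (row.sum(1) == 0).any():
                continue
            pvals.append(chi_square_test(row).p_value)
        ks = stats.kstest(pvals, "uniform")
        # chi-square p-values are discretely supported; demand rough uniformity
        assert ks.statistic < 0.1


def fisher_2x2_enumeration_oracle(table):
    """Two-sided Fisher p via scipy's hypergeometric pmf (probability ordering)."""
    a = np.asarray(table)
    r0 = a[0].sum()
    c0 = a[:, 0].sum()
    n = a.sum()
    pmf = lambda x: stats.hypergeom.pmf(x, n, r0, c0)
    p_obs = pmf(a[0, 0])
    return sum(
        pmf(x)
        for x in range(max(0, r0 + c0 - n), min(r0, c0) + 1)
        if pmf(x) <= p_obs * (1 + 1e-9)
    )


class TestFisher:
    def test_printed_egfr_table(self):
        assert fisher_exact([[2, 13], [4, 6]]) == pytest.approx(0.175, abs=5e-4)

    def test_balanced_table(self):
        assert fisher_exact([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_equals_enumeration_oracle(self, rng):
        for _ in range(20):
            table = rng.integers(0, 12, size=(2, 2))
            if (table.sum(0) == 0).any() or (table.sum(1) == 0).any():
                continue
            assert fisher_exact(table) == pytest.approx(
                fisher_2x2_enumeration_oracle(table), abs=1e-10
            )

    def test_matches_scipy(self, rng):
        for _ in range(20):
            table = rng.integers(1, 15, size=(2, 2))
            _, p = stats.fisher_exact(table)
            assert fisher_exact(table) == pytest.approx(p, abs=1e-9)

    def test_2x3_probabilities_sum_to_one_at_max(self):
        # degenerate margins: every table is at most as probable -> p = 1
        assert fisher_exact([[1, 1, 1], [1, 1, 1]]) == pytest.approx(1.0)

    def test_non_integer_rejected(self):
        with pytest.raises(ValidationError):
            fisher_exact([[1.5, 2], [3, 4]])


class TestDispatch:
    def test_large_expected_uses_chi_square(self):
        assert choose_association_test([[50, 50], [50, 50]]) == "chi_square"

    def test_small_expected_uses_fisher(self):
        # expected counts include 15*4/25 = 2.4 < 5
        assert choose_association_test([[1, 14], [3, 7]]) == "fisher"

    def test_deterministic(self):
        t = [[2, 13], [4, 6]]
        assert choose_association_test(t) == choose_association_test(t)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    st.lists(
        st.floats(min_value=-5, max_value=5, allow_nan=False).map(lambda v: round(v, 1)),
        min_size=1,
        max_size=10,
    )
)
def test_wilcoxon_property_exact_equals_enumeration(diffs):
    d = np.asarray(diffs)
    if (d == 0).all():
        return
    res = wilcoxon_signed_rank(d)
    assert res.p_value == pytest.approx(wilcoxon_enumeration_oracle(d))
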