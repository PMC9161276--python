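"""Nonparametric comparison and contingency machinery.

Paired Wilcoxon signed-rank (exact by enumeration for small n),
Kruskal-Wallis, Pearson chi-square, and a two-sided Fisher exact test by
hypergeometric enumeration, plus the dispatch rule choosing between
chi-square and Fisher from expected counts.

All exact p-values are computed from the full null distribution (sign
enumeration via a generating function for Wilcoxon; margin-fixed table
enumeration for Fisher) rather than distributional approximations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.special import gammaln

from .errors import UndefinedStatisticError, ValidationError

__all__ = [
    "WilcoxonResult",
    "KruskalResult",
    "Chi2Result",
    "wilcoxon_signed_rank",
    "kruskal_wallis",
    "chi_square_test",
    "fisher_exact",
    "choose_association_test",
]

#: largest n for which the exact signed-rank distribution is used
EXACT_WILCOXON_LIMIT = 25


@dataclass
class WilcoxonResult:
    statistic: float      # W = min(W+, W-)
    p_value: float        # two-sided
    n_used: int           # pairs remaining after dropping zero differences
    method: str           # "exact" or "normal"


def _signed_rank_cdf(ranks2: np.ndarray, w2: int) -> float:
    """P(W+ <= w) under random signs, with ranks doubled to integers.

    The distribution of the doubled positive-rank sum is the coefficient
    sequence of prod_i (1 + x^{r_i}) / 2^n.
    """
    total = int(ranks2.sum())
    coeffs = np.zeros(total + 1)
    coeffs[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(coeffs)
        shifted[r:] = coeffs[: total + 1 - r]
        coeffs = coeffs + shifted
    coeffs /= 2.0 ** len(ranks2)
    return float(coeffs[: w2 + 1].sum())


def wilcoxon_signed_rank(
    x: Sequence[float],
    y: Sequence[float] | None = None,
    *,
    method: str = "auto",
) -> WilcoxonResult:
    """Two-sided paired Wilcoxon signed-rank test.

    Zero differences are dropped (Wilcoxon's original rule).  Absolute
    differences are ranked with midranks for ties; W = min(W+, W-).  For
    n <= 25 the exact two-sided p is ``min(1, 2 * P(W+ <= W))`` from the
    enumerated sign distribution; beyond that a normal approximation with
    tie correction and continuity correction is used.
    """
    d = np.asarray(x, dtype=float)
    if y is not None:
        ya = np.asarray(y, dtype=float)
        if ya.shape != d.shape:
            raise ValidationError("paired samples must have equal length")
        d = d - ya
    if np.isnan(d).any():
        raise ValidationError("missing values in paired differences")
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise UndefinedStatisticError(
            "all paired differences are zero; signed-rank test undefined"
        )
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    w = min(w_plus, w_minus)
    if method == "auto":
        method = "exact" if n <= EXACT_WILCOXON_LIMIT else "normal"
    if method == "exact":
        ranks2 = np.rint(2 * ranks).astype(int)
        w2 = int(np.floor(2 * w + 1e-9))
        p = min(1.0, 2.0 * _signed_rank_cdf(ranks2, w2))
    elif method == "normal":
        mu = n * (n + 1) / 4.0
        tie_term = 0.0
        _, counts = np.unique(ranks, return_counts=True)
        tie_term = float(((counts**3 - counts)).sum()) / 48.0
        sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term)
        if sigma == 0:
            raise UndefinedStatisticError("zero variance in signed-rank statistic")
        z = (w - mu + 0.5) / sigma  # continuity correction toward the mean
        p = min(1.0, 2.0 * float(stats.norm.cdf(z)))
    else:
        raise ValidationError(f"unknown method {method!r}")
    return WilcoxonResult(statistic=w, p_value=p, n_used=n, method=method)


@dataclass
class KruskalResult:
    statistic: float
    df: int
    p_value: float


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> KruskalResult:
    """Kruskal-Wallis H over pooled midranks with tie correction."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    arrays = [a for a in arrays if a.size > 0]
    if len(arrays) < 2:
        raise UndefinedStatisticError("need at least two non-empty groups")
    pooled = np.concatenate(arrays)
    n_total = pooled.size
    if n_total < 3:
        raise UndefinedStatisticError("need at least 3 observations in total")
    ranks = stats.rankdata(pooled)
    h = 0.0
    start = 0
    for a in arrays:
        r = ranks[start : start + a.size]
        h += r.sum() ** 2 / a.size
        start += a.size
    h = 12.0 / (n_total * (n_total + 1)) * h - 3 * (n_total + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - float((counts**3 - counts).sum()) / (n_total**3 - n_total)
    if tie == 0:
        raise UndefinedStatisticError("all observations identical")
    h /= tie
    df = len(arrays) - 1
    return KruskalResult(statistic=float(h), df=df, p_value=float(stats.chi2.sf(h, df)))


@dataclass
class Chi2Result:
    statistic: float
    df: int
    p_value: float
    expected: np.ndarray


def _as_table(table) -> np.ndarray:
    a = np.asarray(table)
    if a.ndim != 2 or a.shape[0] < 2 or a.shape[1] < 2:
        raise ValidationError("contingency table must be at least 2x2")
    if np.any(a < 0):
        raise ValidationError("negative counts in contingency table")
    return a


def chi_square_test(table) -> Chi2Result:
    """Pearson chi-square test of independence, no continuity correction."""
    a = _as_table(table).astype(float)
    rows = a.sum(axis=1)
    cols = a.sum(axis=0)
    if np.any(rows == 0):
        raise ValidationError(f"zero row margin at row(s) {np.nonzero(rows == 0)[0].tolist()}")
    if np.any(cols == 0):
        raise ValidationError(
            f"zero column margin at column(s) {np.nonzero(cols == 0)[0].tolist()}"
        )
    expected = np.outer(rows, cols) / a.sum()
    chi2 = float(((a - expected) ** 2 / expected).sum())
    df = (a.shape[0] - 1) * (a.shape[1] - 1)
    return Chi2Result(
        statistic=chi2, df=df, p_value=float(stats.chi2.sf(chi2, df)), expected=expected
    )


def _log_table_prob(a: np.ndarray) -> float:
    """log probability of a 2xc table under fixed margins (multivariate
    hypergeometric): prod(r_i!) prod(c_j!) / (N! prod(a_ij!))."""
    rows = a.sum(axis=1)
    cols = a.sum(axis=0)
    n = a.sum()
    return float(
        gammaln(rows + 1).sum()
        + gammaln(cols + 1).sum()
        - gammaln(n + 1)
        - gammaln(a + 1).sum()
    )


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p for a 2xc table by full enumeration.

    p is the total probability, over all tables with the observed margins,
    of tables no more probable than the observed one (the probability-
    ordering convention).
    """
    a = _as_table(table)
    if not np.issubdtype(a.dtype, np.integer):
        if not np.allclose(a, np.rint(a)):
            raise ValidationError("Fisher exact test requires integer counts")
        a = np.rint(a).astype(int)
    if a.shape[0] != 2:
        raise ValidationError("Fisher enumeration implemented for 2xc tables")
    if a.shape[1] > 6:
        raise ValidationError("Fisher enumeration limited to at most 6 columns")
    r0 = int(a[0].sum())
    cols = a.sum(axis=0).astype(int)
    logp_obs = _log_table_prob(a)
    total = 0.0
    ranges = [range(0, c + 1) for c in cols[:-1]]
    for first in itertools.product(*ranges):
        rest = r0 - sum(first)
        if rest < 0 or rest > cols[-1]:
            continue
        row0 = np.array([*first, rest])
        cand = np.vstack([row0, cols - row0])
        logp = _log_table_prob(cand)
        if logp <= logp_obs + 1e-9:
            total += np.exp(logp)
    return float(min(1.0, total))


def choose_association_test(table) -> str:
    """Dispatch rule: Fisher when any expected count is below 5 (and the
    table is 2xc so the enumeration applies), else Pearson chi-square."""
    a = _as_table(table).astype(float)
    expected = np.outer(a.sum(axis=1), a.sum(axis=0)) / a.sum()
    if (expected < 5).any() and a.shape[0] == 2 and a.shape[1] <= 6:
        return "fisher"
    return "chi_square"
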