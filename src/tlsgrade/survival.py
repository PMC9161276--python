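"""From-scratch survival machinery for disease-free survival analysis.

Implements the product-limit (Kaplan-Meier) estimator, the log-rank test
(two-group and k-group), observed/expected hazard ratios, and
maximally-selected-rank-statistic cutpoint selection for dichotomising
continuous immune features against survival.

Conventions
-----------
* Ties at a time point: events are processed before censorings (standard
  product-limit convention), i.e. a subject censored at t is still at risk
  for the events at t.
* The hazard ratio is the Mantel-Haenszel-style O/E ratio
  ``(O1/E1)/(O2/E2)`` with CI ``exp(log HR +/- 1.96*sqrt(1/E1 + 1/E2))`` —
  the quantity conventionally reported alongside a log-rank test; no
  proportional-hazards regression is fitted anywhere.
* Median survival is the smallest event time with S(t) <= 0.5 and is
  reported as missing ("not reached"), never extrapolated, when the curve
  does not cross 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .errors import ConfigurationError, NoCutpointError, UndefinedStatisticError, ValidationError

__all__ = [
    "KMCurve",
    "LogrankResult",
    "KGroupLogrankResult",
    "CutpointResult",
    "km_curve",
    "logrank_test",
    "logrank_k_groups",
    "max_selected_cutpoint",
    "dichotomize",
    "stratified_analysis",
]


def _as_time_event(time, event) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    if t.size == 0:
        raise ValidationError("empty survival sample")
    if t.shape != e.shape:
        raise ValidationError("time and event must have equal length")
    if np.any(t < 0):
        raise ValidationError("negative survival times")
    if not np.isin(e, (0, 1)).all():
        raise ValidationError("event indicators must be 0/1")
    return t, e


@dataclass
class KMCurve:
    """A product-limit survival curve over the distinct event times."""

    times: np.ndarray            # distinct event times, sorted
    survival: np.ndarray         # S(t) just after each event time
    n_at_risk: np.ndarray        # risk-set size at each event time
    n_events: np.ndarray         # events at each event time
    median: float | None         # None = not reached
    n: int

    def survival_at(self, t: float) -> float:
        """Step-function value S(t)."""
        idx = np.searchsorted(self.times, t, side="right")
        return 1.0 if idx == 0 else float(self.survival[idx - 1])


def km_curve(time: Sequence[float], event: Sequence[int]) -> KMCurve:
    """Kaplan-Meier estimate S(t) = prod_{t_i <= t} (1 - d_i/n_i)."""
    t, e = _as_time_event(time, event)
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    event_times = np.unique(t[e == 1])
    n = t.size
    surv = []
    at_risk = []
    d_list = []
    s = 1.0
    for et in event_times:
        n_i = int(np.sum(t >= et))
        d_i = int(np.sum((t == et) & (e == 1)))
        s *= 1.0 - d_i / n_i
        surv.append(s)
        at_risk.append(n_i)
        d_list.append(d_i)
    surv_arr = np.asarray(surv)
    median = None
    if surv_arr.size:
        crossed = np.nonzero(surv_arr <= 0.5 + 1e-12)[0]
        if crossed.size:
            median = float(event_times[crossed[0]])
    return KMCurve(
        times=event_times,
        survival=surv_arr,
        n_at_risk=np.asarray(at_risk, dtype=int),
        n_events=np.asarray(d_list, dtype=int),
        median=median,
        n=n,
    )


# ---------------------------------------------------------------------------
# log-rank machinery


def _logrank_tables(groups: list[tuple[np.ndarray, np.ndarray]]):
    """Observed, expected and covariance over pooled distinct event times.

    Returns (O, E, V) where O, E are length-k vectors and V is the k x k
    hypergeometric covariance matrix of (O - E).
    """
    k = len(groups)
    all_t = np.concatenate([g[0] for g in groups])
    all_e = np.concatenate([g[1] for g in groups])
    gidx = np.concatenate([np.full(g[0].size, i) for i, g in enumerate(groups)])
    event_times = np.unique(all_t[all_e == 1])
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for et in event_times:
        at_risk = all_t >= et
        n_j = int(at_risk.sum())
        d_j = int(((all_t == et) & (all_e == 1)).sum())
        n_gj = np.array([(at_risk & (gidx == g)).sum() for g in range(k)], dtype=float)
        d_gj = np.array(
            [((all_t == et) & (all_e == 1) & (gidx == g)).sum() for g in range(k)],
            dtype=float,
        )
        O += d_gj
        E += d_j * n_gj / n_j
        if n_j > 1:
            frac = n_gj / n_j
            mult = d_j * (n_j - d_j) / (n_j - 1)
            V += mult * (np.diag(frac) - np.outer(frac, frac))
    return O, E, V


@dataclass
class LogrankResult:
    chi_square: float
    p_value: float
    observed: np.ndarray
    expected: np.ndarray
    hazard_ratio: float
    hr_ci_95: tuple[float, float]
    n: tuple[int, int]


@dataclass
class KGroupLogrankResult:
    chi_square: float
    df: int
    p_value: float
    observed: np.ndarray
    expected: np.ndarray


def logrank_test(
    time_a, event_a, time_b, event_b
) -> LogrankResult:
    """Two-group log-rank test with O/E hazard ratio (group A vs group B)."""
    ta, ea = _as_time_event(time_a, event_a)
    tb, eb = _as_time_event(time_b, event_b)
    if ea.sum() + eb.sum() == 0:
        raise UndefinedStatisticError("no events in either group; log-rank undefined")
    O, E, V = _logrank_tables([(ta, ea), (tb, eb)])
    u = O[0] - E[0]
    v = V[0, 0]
    chi2 = float(u * u / v) if v > 0 else 0.0
    p = float(stats.chi2.sf(chi2, df=1)) if v > 0 else 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        rate_a = O[0] / E[0] if E[0] > 0 else np.inf
        rate_b = O[1] / E[1] if E[1] > 0 else np.inf
        hr = rate_a / rate_b if rate_b > 0 else np.inf
    if np.isfinite(hr) and hr > 0 and E[0] > 0 and E[1] > 0:
        se = np.sqrt(1.0 / E[0] + 1.0 / E[1])
        ci = (float(hr * np.exp(-1.96 * se)), float(hr * np.exp(1.96 * se)))
    else:
        ci = (float("nan"), float("nan"))
    return LogrankResult(
        chi_square=chi2,
        p_value=p,
        observed=O,
        expected=E,
        hazard_ratio=float(hr),
        hr_ci_95=ci,
        n=(ta.size, tb.size),
    )


def logrank_k_groups(groups: Iterable[tuple[Sequence[float], Sequence[int]]]) -> KGroupLogrankResult:
    """k-group log-rank test; specialises to the two-group chi-square at k=2."""
    parsed = [_as_time_event(t, e) for t, e in groups]
    if len(parsed) < 2:
        raise ValidationError("need at least two groups")
    if sum(int(e.sum()) for _, e in parsed) == 0:
        raise UndefinedStatisticError("no events in any group; log-rank undefined")
    O, E, V = _logrank_tables(parsed)
    k = len(parsed)
    u = (O - E)[: k - 1]
    v = V[: k - 1, : k - 1]
    # pinv guards degenerate strata (e.g. a group fully censored before all events)
    chi2 = float(u @ np.linalg.pinv(v) @ u)
    df = k - 1
    return KGroupLogrankResult(
        chi_square=chi2, df=df, p_value=float(stats.chi2.sf(chi2, df=df)), observed=O, expected=E
    )


# ---------------------------------------------------------------------------
# maximally selected rank statistics


def _admissible_cutoffs(values: np.ndarray, minprop: float) -> np.ndarray:
    """Observed values usable as cutoffs (split: >= cutoff is "high") whose
    two sides both contain at least ceil(minprop * n) subjects."""
    n = values.size
    min_group = int(np.ceil(minprop * n))
    cand = np.unique(values)
    n_high = np.array([(values >= c).sum() for c in cand])
    n_low = n - n_high
    ok = (n_high >= min_group) & (n_low >= min_group)
    return cand[ok]


def _split_statistics(
    values: np.ndarray, time: np.ndarray, event: np.ndarray, cutoffs: np.ndarray
) -> np.ndarray:
    """Standardised log-rank statistic |U|/sqrt(V) for every candidate split,
    vectorised over candidates."""
    order = np.argsort(time, kind="stable")
    t, e, v = time[order], event[order], values[order]
    n = t.size
    Z = (v[:, None] >= cutoffs[None, :]).astype(float)  # n x C membership
    # suffix counts: number of "high" subjects with time >= t_i
    suffix = np.cumsum(Z[::-1], axis=0)[::-1]
    starts = np.nonzero(np.r_[True, t[1:] != t[:-1]])[0]  # first index of each distinct time
    d_all = np.add.reduceat(e, starts)                    # events at each distinct time
    d_high = np.add.reduceat(Z * e[:, None], starts, axis=0)
    n_at_risk = n - starts
    n_high = suffix[starts]
    keep = d_all > 0
    d_all = d_all[keep]
    d_high = d_high[keep]
    n_at_risk = n_at_risk[keep].astype(float)
    n_high = n_high[keep]
    frac = n_high / n_at_risk[:, None]
    U = (d_high - d_all[:, None] * frac).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        mult = np.where(
            n_at_risk > 1, d_all * (n_at_risk - d_all) / (n_at_risk - 1), 0.0
        )
    V = (mult[:, None] * frac * (1.0 - frac)).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(V > 0, np.abs(U) / np.sqrt(V), 0.0)
    return z


@dataclass
class CutpointResult:
    cutoff: float
    statistic: float            # standardised log-rank statistic at the cutoff
    minprop: float
    p_value: float | None       # permutation p; None if n_permutations == 0
    candidates: np.ndarray = field(repr=False, default=None)
    statistics: np.ndarray = field(repr=False, default=None)


def max_selected_cutpoint(
    values: Sequence[float],
    time: Sequence[float],
    event: Sequence[int],
    *,
    minprop: float = 0.1,
    n_permutations: int = 1000,
    random_state: int | np.random.Generator | None = None,
) -> CutpointResult:
    """Maximally selected rank statistic cutoff for a continuous feature.

    Candidate cutoffs are the observed values whose induced >=/< split keeps
    at least ``minprop`` of subjects on both sides; for each, the
    standardised two-group log-rank statistic is computed and the argmax
    returned (ties broken toward the smallest cutoff).  The p-value is
    estimated by permuting the feature against the (time, event) pairs,
    which simulates the null of no feature-outcome association while
    preserving both marginals.
    """
    vals = np.asarray(values, dtype=float)
    t, e = _as_time_event(time, event)
    if vals.shape != t.shape:
        raise ValidationError("values and survival records must align")
    if np.isnan(vals).any():
        raise ValidationError("missing feature values must be excluded before cutpoint search")
    if vals.size < 10:
        raise NoCutpointError(f"need at least 10 subjects, got {vals.size}")
    if not 0 < minprop < 0.5:
        raise ConfigurationError("minprop must be in (0, 0.5)")
    if np.unique(vals).size == 1:
        raise NoCutpointError("constant feature; no cutpoint exists")
    if e.sum() == 0:
        raise UndefinedStatisticError("no events; cutpoint statistic undefined")
    cutoffs = _admissible_cutoffs(vals, minprop)
    if cutoffs.size == 0:
        raise NoCutpointError("no admissible candidate cutoff under minprop")
    z = _split_statistics(vals, t, e, cutoffs)
    best = z.max()
    idx = int(np.nonzero(z >= best - 1e-9)[0][0])  # smallest cutoff among ties
    p = None
    if n_permutations > 0:
        rng = (
            random_state
            if isinstance(random_state, np.random.Generator)
            else np.random.default_rng(random_state)
        )
        hits = 0
        for _ in range(n_permutations):
            perm = rng.permutation(vals)
            zp = _split_statistics(perm, t, e, _admissible_cutoffs(perm, minprop))
            if zp.size and zp.max() >= best - 1e-12:
                hits += 1
        p = (hits + 1) / (n_permutations + 1)
    return CutpointResult(
        cutoff=float(cutoffs[idx]),
        statistic=float(z[idx]),
        minprop=minprop,
        p_value=p,
        candidates=cutoffs,
        statistics=z,
    )


def dichotomize(values: Sequence[float], cutoff: float) -> np.ndarray:
    """Label values ``>= cutoff`` as "high", below as "low" (the ">= cutoff
    vs < cutoff" stratum convention).  NaN values yield None and must be
    excluded downstream, never imputed."""
    if not np.isfinite(cutoff):
        raise ValidationError("cutoff must be finite")
    vals = np.asarray(values, dtype=float)
    out = np.where(vals >= cutoff, "high", "low").astype(object)
    out[np.isnan(vals)] = None
    return out


def stratified_analysis(
    time: Sequence[float],
    event: Sequence[int],
    labels: Sequence,
    *,
    min_stratum: int = 2,
) -> dict:
    """Per-stratum KM curves/medians plus all pairwise log-rank comparisons.

    Strata with fewer than ``min_stratum`` subjects are flagged and excluded
    from pairwise testing.  Returns a dict with "strata" (label -> {n,
    median, curve}), "pairwise" (list of comparison records) and "excluded".
    """
    t, e = _as_time_event(time, event)
    lab = np.asarray(labels, dtype=object)
    if lab.shape != t.shape:
        raise ValidationError("labels must align with survival records")
    keep = np.array([l is not None for l in lab])
    t, e, lab = t[keep], e[keep], lab[keep]
    strata: dict = {}
    excluded: list = []
    for name in sorted(set(lab), key=str):
        mask = lab == name
        n = int(mask.sum())
        if n < min_stratum:
            excluded.append(str(name))
            continue
        curve = km_curve(t[mask], e[mask])
        strata[str(name)] = {"n": n, "median": curve.median, "curve": curve}
    names = list(strata)
    pairwise = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            ma = lab == a
            mb = lab == b
            try:
                res = logrank_test(t[ma], e[ma], t[mb], e[mb])
            except UndefinedStatisticError:
                continue
            pairwise.append(
                {
                    "group_a": a,
                    "group_b": b,
                    "chi_square": res.chi_square,
                    "p_value": res.p_value,
                    "hazard_ratio": res.hazard_ratio,
                    "hr_ci_95": list(res.hr_ci_95),
                    "n": list(res.n),
                }
            )
    return {"strata": strata, "pairwise": pairwise, "excluded": excluded}
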