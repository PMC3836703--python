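"""Statistical primitives shared by every stage of the screen.

Pure computation on numpy arrays: Pearson/Spearman correlation with a
two-sided significance from the t transform, the Kaplan-Meier
product-limit estimator, a fast two-group log-rank test, the two-sided
Mann-Whitney rank-sum test used by the abundance filter, and the
Bonferroni family-wise threshold.

All tests return plain dataclasses; degenerate inputs (zero variance, no
observed events) yield flagged results rather than NaNs so that callers
can keep book-keeping explicit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "CorrelationResult",
    "SurvivalCurve",
    "LogrankResult",
    "pearson_with_p",
    "correlation",
    "km_curve",
    "logrank_test",
    "ranksum_test",
    "bonferroni_threshold",
]


@dataclass(frozen=True)
class CorrelationResult:
    """Correlation coefficient with its two-sided significance.

    ``degenerate`` marks results computed on input where the coefficient
    is undefined (fewer than 3 samples available to the caller, or a
    zero-variance vector); such results carry r=0, p=1 and must never be
    interpreted as evidence of independence.
    """

    r: float
    p: float
    n: int
    degenerate: bool = False


@dataclass(frozen=True)
class SurvivalCurve:
    """Product-limit survival estimate evaluated after each event time."""

    times: np.ndarray      # distinct times at which >=1 event occurred
    survival: np.ndarray   # S(t) just after each event time
    at_risk: np.ndarray    # risk-set size just before each event time

    def __post_init__(self) -> None:
        if not (len(self.times) == len(self.survival) == len(self.at_risk)):
            raise ValueError("times, survival and at_risk must have equal length")


@dataclass(frozen=True)
class LogrankResult:
    chi2: float
    p: float
    n1: int
    n2: int
    degenerate: bool = False


def _t_pvalue(r: float, n: int) -> float:
    """Two-sided p for a Pearson r via t = r*sqrt((n-2)/(1-r^2)), df = n-2."""
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * sps.t.sf(abs(t), n - 2))


def pearson_with_p(x, y) -> CorrelationResult:
    """Pearson product-moment correlation with a two-sided t-transform p.

    Parameters
    ----------
    x, y : array-like, equal length, n >= 3.

    Returns
    -------
    CorrelationResult
        Degenerate (r=0, p=1) when either vector has zero variance.

    Raises
    ------
    ValueError
        On length mismatch or n < 3.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    n = x.size
    if n < 3:
        raise ValueError("correlation requires at least 3 samples")
    xc = x - x.mean()
    yc = y - y.mean()
    vx = float(xc @ xc)
    vy = float(yc @ yc)
    if vx <= 0.0 or vy <= 0.0:
        return CorrelationResult(r=0.0, p=1.0, n=n, degenerate=True)
    r = float(xc @ yc) / np.sqrt(vx * vy)
    r = float(np.clip(r, -1.0, 1.0))
    return CorrelationResult(r=r, p=_t_pvalue(r, n), n=n)


def spearman_with_p(x, y) -> CorrelationResult:
    """Spearman rank correlation with the same t-transform significance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    if x.size < 3:
        raise ValueError("correlation requires at least 3 samples")
    return pearson_with_p(sps.rankdata(x), sps.rankdata(y))


def correlation(x, y, method: str = "pearson") -> CorrelationResult:
    """Dispatch on the configured correlation method."""
    if method == "pearson":
        return pearson_with_p(x, y)
    if method == "spearman":
        return spearman_with_p(x, y)
    raise ValueError(f"unknown correlation method: {method!r}")


def km_curve(times, events) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimate.

    Censored subjects leave the risk set after their censoring time;
    ties between events and censorings at the same time are resolved
    events-first (both remain in the risk set at that time).
    """
    from lifelines import KaplanMeierFitter

    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValueError("empty input")
    if times.shape != events.shape:
        raise ValueError("times and events must have equal length")
    if np.any(times < 0):
        raise ValueError("negative survival time")

    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    table = kmf.event_table
    ev = table[table["observed"] > 0]
    if len(ev) == 0:
        return SurvivalCurve(
            times=np.empty(0), survival=np.empty(0), at_risk=np.empty(0, dtype=int)
        )
    t = ev.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.loc[ev.index, kmf.survival_function_.columns[0]]
    return SurvivalCurve(
        times=t,
        survival=surv.to_numpy(dtype=float),
        at_risk=ev["at_risk"].to_numpy(dtype=int),
    )


def _logrank_terms(times, events, labels):
    """Per-event-time (d1, d, n1, n) arrays for the two-group log-rank.

    Sorted ascending in time; the risk set at an event time contains every
    subject with time >= that time (events-first tie handling).
    """
    order = np.argsort(times, kind="stable")
    t = times[order]
    e = events[order]
    g = labels[order]
    n = t.size
    # first index of each distinct time
    new_t = np.empty(n, dtype=bool)
    new_t[0] = True
    new_t[1:] = t[1:] != t[:-1]
    starts = np.flatnonzero(new_t)
    d = np.add.reduceat(e.astype(np.int64), starts)
    d1 = np.add.reduceat((e & g).astype(np.int64), starts)
    n_at_risk = n - starts
    g_cum = np.concatenate(([0], np.cumsum(g.astype(np.int64))))
    n1_at_risk = int(g.sum()) - g_cum[starts]
    keep = d > 0
    return d1[keep], d[keep], n1_at_risk[keep], n_at_risk[keep]


def logrank_test(times, events, labels) -> LogrankResult:
    """Two-group log-rank test.

    At each distinct event time the observed minus expected number of
    events in group 1 is accumulated with the hypergeometric variance;
    chi2 = (sum O-E)^2 / sum V, p from chi-square with 1 df.

    Parameters
    ----------
    times, events : survival times (days) and event indicators.
    labels : boolean vector, True = group 1. Both labels must be present.

    Returns
    -------
    LogrankResult
        Degenerate (chi2=0, p=1) when no events are observed or when the
        variance vanishes (e.g. all events at times where one group has
        left the risk set entirely).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    labels = np.asarray(labels, dtype=bool)
    if not (times.shape == events.shape == labels.shape):
        raise ValueError("times, events and labels must have equal length")
    n1 = int(labels.sum())
    n2 = int((~labels).sum())
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    if not events.any():
        return LogrankResult(chi2=0.0, p=1.0, n1=n1, n2=n2, degenerate=True)

    d1, d, r1, r = _logrank_terms(times, events, labels)
    frac = r1 / r
    o_minus_e = float(np.sum(d1 - d * frac))
    with np.errstate(invalid="ignore", divide="ignore"):
        v = d * frac * (1.0 - frac) * (r - d) / np.where(r > 1, r - 1, 1)
    var = float(np.sum(v))
    if var <= 0.0:
        return LogrankResult(chi2=0.0, p=1.0, n1=n1, n2=n2, degenerate=True)
    chi2 = o_minus_e * o_minus_e / var
    return LogrankResult(chi2=chi2, p=float(sps.chi2.sf(chi2, 1)), n1=n1, n2=n2)


def ranksum_test(a, b, alternative: str = "two-sided") -> float:
    """Mann-Whitney U p-value (tie-corrected), default two-sided.

    Used by the abundance filter to ask whether the expression level of a
    gene or miR differs between the two patient groups.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need at least 2 observations")
    res = sps.mannwhitneyu(a, b, alternative=alternative, method="auto")
    return float(res.pvalue)


def bonferroni_threshold(m: int, alpha: float = 0.05) -> float:
    """Family-wise significance threshold alpha / m."""
    if m < 1:
        raise ValueError("m must be a positive integer")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    return alpha / m
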