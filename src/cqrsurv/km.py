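"""Product-limit survival estimation and the k-sample log-rank test.

Implements the Kaplan-Meier estimator with Greenwood variance, step-function
evaluation with confidence intervals, median survival, restricted-mean
survival time (the only mean survival estimable under heavy censoring), and
the standard observed-minus-expected log-rank chi-square.

Tie convention: subjects censored exactly at an event time remain at risk
for that event (the dominant convention; at-risk counts use ``Y >= t``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DataError


@dataclass
class SurvivalCurve:
    """Right-continuous step estimate of S(t) over the distinct event times.

    ``surv[j]`` is the estimate just after ``times[j]``; ``var_terms`` holds
    the cumulative Greenwood sum ``sum d/(n(n-d))`` so that
    ``se = surv * sqrt(var_terms)``.
    """

    times: np.ndarray
    n_risk: np.ndarray
    n_event: np.ndarray
    surv: np.ndarray
    var_terms: np.ndarray
    n: int
    max_followup: float
    no_events: bool = False

    @property
    def se(self) -> np.ndarray:
        return self.surv * np.sqrt(self.var_terms)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "n_risk": self.n_risk,
                "n_event": self.n_event,
                "surv": self.surv,
                "se": self.se,
            }
        )


@dataclass
class LogRankResult:
    statistic: float
    df: int
    p_value: float
    observed: np.ndarray = field(default_factory=lambda: np.array([]))
    expected: np.ndarray = field(default_factory=lambda: np.array([]))


def _as_arrays(times, events) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=int)
    if t.shape != d.shape or t.ndim != 1:
        raise DataError("times and events must be equal-length 1-d sequences")
    if len(t) == 0:
        raise DataError("empty sample")
    if np.any(t <= 0):
        raise DataError("all times must be > 0")
    if not np.isin(d, (0, 1)).all():
        raise DataError("events must be 0/1")
    return t, d


def km_fit(times, events) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimate over the distinct event times."""
    t, d = _as_arrays(times, events)
    n = len(t)
    order = np.argsort(t, kind="stable")
    ts, ds = t[order], d[order]

    if ds.sum() == 0:
        warnings.warn("no events at all: survival is identically 1", stacklevel=2)
        return SurvivalCurve(
            times=np.array([]),
            n_risk=np.array([], dtype=int),
            n_event=np.array([], dtype=int),
            surv=np.array([]),
            var_terms=np.array([]),
            n=n,
            max_followup=float(ts[-1]),
            no_events=True,
        )

    ev_times, first_idx = np.unique(ts[ds == 1], return_index=True)
    d_j = np.bincount(np.searchsorted(ev_times, ts[ds == 1]))
    # at risk: Y >= t_j (censored ties included)
    n_j = n - np.searchsorted(ts, ev_times, side="left")
    frac = d_j / n_j
    surv = np.cumprod(1.0 - frac)
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(n_j > d_j, d_j / (n_j * (n_j - d_j)), np.inf)
    var_terms = np.cumsum(g)
    return SurvivalCurve(
        times=ev_times,
        n_risk=n_j.astype(int),
        n_event=d_j.astype(int),
        surv=surv,
        var_terms=var_terms,
        n=n,
        max_followup=float(ts[-1]),
    )


def survival_at(
    curve: SurvivalCurve,
    t: float | np.ndarray,
    *,
    return_ci: bool = False,
    conf_level: float = 0.95,
    ci_method: str = "log",
):
    """Right-continuous evaluation of the fitted step function at ``t``.

    Beyond the last observed follow-up the last value is carried forward with
    an extrapolation warning.  With ``return_ci=True`` returns
    ``(surv, lower, upper)`` using log-transformed Greenwood intervals by
    default (plain Greenwood with ``ci_method="plain"``).
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0):
        raise DataError("t must be >= 0")
    if np.any(t_arr > curve.max_followup):
        warnings.warn(
            "evaluation beyond the last observed time: last value carried forward",
            stacklevel=2,
        )
    idx = np.searchsorted(curve.times, t_arr, side="right") - 1
    s = np.where(idx >= 0, np.concatenate([[1.0], curve.surv])[idx + 1], 1.0)
    if curve.no_events:
        s = np.ones_like(t_arr)
    if not return_ci:
        return s if np.ndim(t) else float(s[0])

    v = np.where(idx >= 0, np.concatenate([[0.0], curve.var_terms])[idx + 1], 0.0)
    zq = stats.norm.ppf(0.5 + conf_level / 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        if ci_method == "log":
            # CI on log S: S * exp(+/- z * sqrt(v))  (stays within (0, 1] after clip)
            lo = s * np.exp(-zq * np.sqrt(v))
            hi = np.minimum(s * np.exp(zq * np.sqrt(v)), 1.0)
        elif ci_method == "plain":
            half = zq * s * np.sqrt(v)
            lo, hi = np.clip(s - half, 0, 1), np.clip(s + half, 0, 1)
        else:
            raise DataError(f"unknown ci_method {ci_method!r}")
    lo = np.where(s > 0, lo, 0.0)
    if np.ndim(t):
        return s, lo, hi
    return float(s[0]), float(lo[0]), float(hi[0])


def median_survival(curve: SurvivalCurve) -> float:
    """Smallest event time with S(t) <= 0.5; NaN when the curve never
    reaches 0.5 within follow-up (undefined median)."""
    if curve.no_events:
        return float("nan")
    hit = np.nonzero(curve.surv <= 0.5)[0]
    return float(curve.times[hit[0]]) if len(hit) else float("nan")


def restricted_mean(curve: SurvivalCurve, tau_max: float) -> tuple[float, float]:
    """Restricted mean survival time: area under S on [0, tau_max], with the
    standard Kaplan-Meier RMST standard error.

    ``tau_max`` beyond the last observed follow-up is truncated there with a
    warning (the curve is unknown further out).
    """
    if tau_max <= 0:
        raise DataError("tau_max must be > 0")
    if tau_max > curve.max_followup:
        warnings.warn("tau_max beyond last observed time: truncated", stacklevel=2)
        tau_max = curve.max_followup
    if curve.no_events:
        return float(tau_max), 0.0

    inside = curve.times <= tau_max
    ts = np.concatenate([[0.0], curve.times[inside], [tau_max]])
    ss = np.concatenate([[1.0], curve.surv[inside]])
    rmst = float(np.sum(ss * np.diff(ts)))

    # variance: sum over event times t_j <= tau_max of A_j^2 d/(n(n-d)),
    # A_j = area under S from t_j to tau_max
    areas = np.cumsum((ss * np.diff(ts))[::-1])[::-1]  # area from ts[k] to tau_max
    a_j = areas[1:]  # from each event time onward
    d = curve.n_event[inside]
    r = curve.n_risk[inside]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(r > d, a_j**2 * d / (r * (r - d)), np.inf)
    var = float(np.sum(terms)) if len(terms) else 0.0
    return rmst, float(np.sqrt(var))


def logrank_test(groups) -> LogRankResult:
    """k-sample log-rank test.

    ``groups`` is a sequence of ``(times, events)`` pairs, one per group.
    Observed-minus-expected event counts are accumulated over the pooled
    distinct event times with hypergeometric variance, giving a chi-square
    statistic on k-1 degrees of freedom.
    """
    if len(groups) < 2:
        raise DataError("need at least two groups")
    parsed = [_as_arrays(t, d) for t, d in groups]
    k = len(parsed)
    all_t = np.concatenate([t for t, _ in parsed])
    all_d = np.concatenate([d for _, d in parsed])
    gid = np.concatenate([np.full(len(t), i) for i, (t, _) in enumerate(parsed)])

    ev_times = np.unique(all_t[all_d == 1])
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for t0 in ev_times:
        at_risk = all_t >= t0
        n_tot = at_risk.sum()
        d_tot = int(((all_t == t0) & (all_d == 1)).sum())
        n_g = np.bincount(gid[at_risk], minlength=k).astype(float)
        d_g = np.bincount(gid[(all_t == t0) & (all_d == 1)], minlength=k).astype(float)
        O += d_g
        E += d_tot * n_g / n_tot
        if n_tot > 1:
            p = n_g / n_tot
            hyper = d_tot * (n_tot - d_tot) / (n_tot - 1)
            V += hyper * (np.diag(p) - np.outer(p, p))

    diff = (O - E)[: k - 1]
    Vsub = V[: k - 1, : k - 1]
    try:
        stat = float(diff @ np.linalg.solve(Vsub, diff))
    except np.linalg.LinAlgError:
        stat = float(diff @ np.linalg.pinv(Vsub) @ diff)
    stat = max(stat, 0.0)
    df = k - 1
    return LogRankResult(
        statistic=stat,
        df=df,
        p_value=float(stats.chi2.sf(stat, df)),
        observed=O,
        expected=E,
    )
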