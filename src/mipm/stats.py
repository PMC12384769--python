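"""Low-level survival statistics shared by model building and evaluation.

These are authored here (rather than called from a survival package)
because the cutpoint search needs a fast vectorizable two-group log-rank
statistic and the penalized-Cox cross-validation needs a standalone partial
log-likelihood evaluator; both are cross-checked against lifelines in the
test suite.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

__all__ = ["logrank_statistic", "km_estimate", "km_survival_at", "cox_partial_loglik"]


def logrank_statistic(
    time: np.ndarray, event: np.ndarray, in_group1: np.ndarray
) -> tuple[float, float, float]:
    """Two-group log-rank test.

    Returns ``(z, chi2, p)`` where ``z = (O1 - E1) / sqrt(V)`` is the
    standardized statistic (sign: positive when group 1 has more events
    than expected) and ``chi2 = z**2`` is referred to a 1-df chi-square.
    Degenerate risk sets (no variance) give z = 0, p = 1.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    g1 = np.asarray(in_group1, bool)
    if g1.all() or not g1.any():
        raise ValueError("both groups must be non-empty")

    et = np.unique(time[event == 1])
    o_minus_e = 0.0
    var = 0.0
    # risk-set counts via searchsorted on sorted times
    st = np.sort(time)
    st1 = np.sort(time[g1])
    ev_times = time[event == 1]
    ev_g1 = g1[event == 1]
    for t in et:
        n = len(st) - np.searchsorted(st, t, side="left")
        n1 = len(st1) - np.searchsorted(st1, t, side="left")
        d = int((ev_times == t).sum())
        d1 = int(ev_g1[ev_times == t].sum())
        if n <= 1:
            continue
        e1 = d * n1 / n
        v = d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
        o_minus_e += d1 - e1
        var += v
    if var <= 0:
        return 0.0, 0.0, 1.0
    z = o_minus_e / np.sqrt(var)
    chi2 = z * z
    p = float(chi2_dist.sf(chi2, 1))
    return float(z), float(chi2), p


def km_estimate(time: np.ndarray, event: np.ndarray) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimate with Greenwood variance.

    Returns a DataFrame indexed by distinct event times with columns
    ``at_risk``, ``events``, ``survival`` and ``variance`` (Greenwood).
    Censoring at a tied time is handled after the events at that time
    (the standard convention).
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    if len(time) == 0:
        raise ValueError("empty sample")
    et = np.unique(time[event == 1])
    st = np.sort(time)
    rows = []
    surv = 1.0
    gw = 0.0
    for t in et:
        n = len(st) - np.searchsorted(st, t, side="left")
        d = int(((time == t) & (event == 1)).sum())
        surv *= 1.0 - d / n
        if n > d:
            gw += d / (n * (n - d))
        rows.append((t, n, d, surv, surv * surv * gw))
    return pd.DataFrame(
        rows, columns=["time", "at_risk", "events", "survival", "variance"]
    ).set_index("time")


def km_survival_at(km: pd.DataFrame, t: float) -> tuple[float, float]:
    """KM survival and Greenwood variance at time ``t`` (step function)."""
    prior = km.loc[km.index <= t]
    if prior.empty:
        return 1.0, 0.0
    last = prior.iloc[-1]
    return float(last["survival"]), float(last["variance"])


def cox_partial_loglik(
    time: np.ndarray, event: np.ndarray, lp: np.ndarray, ties: str = "efron"
) -> float:
    """Cox partial log-likelihood of a linear predictor (Efron or Breslow)."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    lp = np.asarray(lp, float)
    order = np.argsort(time, kind="stable")
    time, event, lp = time[order], event[order], lp[order]
    theta = np.exp(lp)
    # cumulative risk-set sums from the right
    rev_cum = np.cumsum(theta[::-1])[::-1]
    ll = 0.0
    i = 0
    n = len(time)
    while i < n:
        j = i
        while j < n and time[j] == time[i]:
            j += 1
        ev = np.arange(i, j)[event[i:j] == 1]
        d = len(ev)
        if d > 0:
            risk = rev_cum[i]
            tied = theta[ev].sum()
            ll += lp[ev].sum()
            if ties == "efron":
                for k in range(d):
                    ll -= np.log(risk - (k / d) * tied)
            elif ties == "breslow":
                ll -= d * np.log(risk)
            else:
                raise ValueError("ties must be 'efron' or 'breslow'")
        i = j
    return float(ll)
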