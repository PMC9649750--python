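"""Kaplan–Meier estimation and log-rank testing for survival contrasts.

Implements the product-limit estimator S(t) = prod_{t_i <= t} (1 - d_i/n_i)
and the k-group log-rank test in its variance–covariance form: at each
distinct event time the observed group event counts are compared with
their expectation under the pooled hazard, the hypergeometric covariance
is accumulated, and the quadratic form on k-1 groups is chi-square with
k-1 degrees of freedom.

Single-gene contrasts split a bulk cohort at the cohort median expression
(ties go to the low group, so an odd cohort puts the extra sample low).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from cervstrat.io_formats import BulkCohort


@dataclass
class KMEstimate:
    """Kaplan–Meier curve for one group over its distinct event times."""

    group: object
    times: np.ndarray  # distinct event times, increasing (0 prepended)
    survival: np.ndarray  # S(t) at those times; S(0) = 1
    at_risk: np.ndarray  # n at risk just before each time
    n_events: np.ndarray

    def survival_at(self, t: float) -> float:
        """Step-function evaluation of S(t)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return float(self.survival[max(idx, 0)])

    def median(self) -> float:
        """Smallest event time with S(t) <= 0.5 (inf if never reached)."""
        below = np.where(self.survival <= 0.5)[0]
        return float(self.times[below[0]]) if len(below) else np.inf


@dataclass
class LogRankResult:
    chi_square: float
    df: int
    p_value: float


def _km_one_group(times: np.ndarray, events: np.ndarray, group) -> KMEstimate:
    order = np.argsort(times, kind="stable")
    t, e = times[order], events[order]
    event_times = np.unique(t[e == 1])
    n = len(t)
    surv, at_risk, d_out = [1.0], [n], [0]
    s = 1.0
    for et in event_times:
        ni = int((t >= et).sum())
        di = int(((t == et) & (e == 1)).sum())
        s *= 1.0 - di / ni
        surv.append(s)
        at_risk.append(ni)
        d_out.append(di)
    if len(event_times) == 0:
        warnings.warn(f"group {group!r}: no events observed; curve is flat at 1", stacklevel=3)
    return KMEstimate(
        group=group,
        times=np.concatenate([[0.0], event_times]),
        survival=np.asarray(surv),
        at_risk=np.asarray(at_risk),
        n_events=np.asarray(d_out),
    )


def km_estimate(times, events, groups=None) -> dict:
    """Product-limit survival curves, one per group.

    Parameters
    ----------
    times, events
        Follow-up times (> 0) and binary event indicators.
    groups
        Optional per-subject group labels; default: one pooled group.

    Returns
    -------
    dict mapping group label to :class:`KMEstimate`.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    if (times <= 0).any():
        raise ValueError("times must be positive")
    if not np.isin(events, [0, 1]).all():
        raise ValueError("events must be binary")
    if groups is None:
        groups = np.zeros(len(times), dtype=int)
    groups = np.asarray(groups)
    return {
        g: _km_one_group(times[groups == g], events[groups == g].astype(int), g)
        for g in pd.unique(groups)
    }


def logrank_test(times, events, groups) -> LogRankResult:
    """k-group log-rank test of equal hazards.

    chi-square = x' V^-1 x with x = O - E on the first k-1 groups, where
    at each distinct event time O, E and the hypergeometric covariance V
    are accumulated over groups.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    groups = np.asarray(groups)
    uniq = pd.unique(groups)
    k = len(uniq)
    if k < 2:
        raise ValueError("log-rank requires at least 2 groups")
    for g in uniq:
        if (groups == g).sum() == 0:
            raise ValueError(f"group {g!r} has zero subjects")
    if events.sum() == 0:
        raise ValueError("log-rank requires at least one observed event")

    gidx = {g: i for i, g in enumerate(uniq)}
    gi = np.array([gidx[g] for g in groups])
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for et in np.unique(times[events == 1]):
        at_risk = times >= et
        n = int(at_risk.sum())
        d = int(((times == et) & (events == 1)).sum())
        n_g = np.bincount(gi[at_risk], minlength=k).astype(float)
        d_g = np.bincount(gi[(times == et) & (events == 1)], minlength=k).astype(float)
        O += d_g
        E += d * n_g / n
        if n > 1:
            w = d * (n - d) / (n - 1)
            p = n_g / n
            V += w * (np.diag(p) - np.outer(p, p))
    x = (O - E)[: k - 1]
    Vsub = V[: k - 1, : k - 1]
    chi2 = float(x @ np.linalg.pinv(Vsub) @ x)
    chi2 = max(chi2, 0.0)
    p = float(stats.chi2.sf(chi2, k - 1))
    return LogRankResult(chi_square=chi2, df=k - 1, p_value=p)


def median_split_survival(
    bulk: BulkCohort, gene: str, quantile: float = 0.5
) -> tuple[dict, LogRankResult]:
    """KM + log-rank comparing high vs low expressors of one gene.

    The cohort is split at the ``quantile`` (default median) of the gene's
    expression; samples exactly at the cut go to the low group.
    """
    if gene not in bulk.expression.columns:
        raise KeyError(f"gene {gene!r} not in cohort")
    if bulk.n_samples < 4:
        raise ValueError("need at least 4 samples for a split contrast")
    expr = bulk.expression[gene]
    if expr.nunique() == 1:
        raise ValueError(f"gene {gene!r} is constant; split is degenerate")
    cut = expr.quantile(quantile)
    labels = np.where(expr <= cut, "low", "high")
    if len(np.unique(labels)) < 2:
        raise ValueError(f"gene {gene!r}: all samples fall on one side of the cut")
    kms = km_estimate(bulk.survival_time.values, bulk.event.values, labels)
    lr = logrank_test(bulk.survival_time.values, bulk.event.values, labels)
    return kms, lr
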