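"""Nonparametric survival statistics: Nelson-Aalen, log-rank, concordance.

These primitives are the building blocks of the survival forest: the
Nelson-Aalen estimator supplies terminal-node cumulative hazards, the
standardized two-sample log-rank statistic is the node-splitting criterion,
and Harrell's concordance measures out-of-bag ranking error. Time is "days
until ICU exit", the event is discharge, and death is right censoring; a
censored case leaves the risk set after its censoring time (cases censored
exactly at an event time are still at risk at that time).
"""

from __future__ import annotations

import numpy as np

from .stepfun import StepFunction

__all__ = ["nelson_aalen", "log_rank_statistic", "harrell_concordance"]


def _as_time_event(times, events) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.ndim != 1 or t.shape != e.shape:
        raise ValueError("times and events must be 1-D arrays of equal length")
    if len(t) == 0:
        raise ValueError("at least one observation is required")
    if np.any(t < 0):
        raise ValueError("times must be >= 0")
    return t, e


def nelson_aalen(times, events) -> StepFunction:
    """Nelson-Aalen cumulative hazard estimator.

    At each distinct event time ``t_l`` the cumulative hazard increments by
    ``d_l / I_l`` — events at ``t_l`` over the number of cases still at risk
    (observation time >= ``t_l``). Returns a right-continuous step function
    with a knot per distinct event time; with no events anywhere it is
    identically zero.
    """
    t, e = _as_time_event(times, events)
    event_times, d = np.unique(t[e], return_counts=True)
    if len(event_times) == 0:
        return StepFunction(np.empty(0), np.empty(0))
    t_sorted = np.sort(t)
    at_risk = len(t) - np.searchsorted(t_sorted, event_times, side="left")
    return StepFunction(event_times, np.cumsum(d / at_risk))


def log_rank_statistic(times, events, left_mask) -> float:
    """Standardized two-sample log-rank statistic.

    Positive when the *left* group experiences more events than expected
    under the null of a common hazard; swapping groups negates the value.
    Survival-tree splits maximize its absolute value.

    Raises if either group is empty or the statistic is degenerate (no
    events, or no variance — e.g. every case in one group by event time).
    """
    t, e = _as_time_event(times, events)
    left = np.asarray(left_mask, dtype=bool)
    if left.shape != t.shape:
        raise ValueError("left_mask must match times in shape")
    if not left.any() or left.all():
        raise ValueError("both groups must be non-empty")
    event_times = np.unique(t[e])
    if len(event_times) == 0:
        raise ValueError("log-rank statistic undefined with no events")
    u = 0.0
    var = 0.0
    for tl in event_times:
        at = t >= tl
        n = np.sum(at)
        n1 = np.sum(at & left)
        ev = e & (t == tl)
        d = np.sum(ev)
        d1 = np.sum(ev & left)
        u += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1.0 - n1 / n) * (n - d) / (n - 1.0)
    if var <= 0.0:
        raise ValueError("log-rank statistic degenerate (zero variance)")
    return float(u / np.sqrt(var))


def harrell_concordance(times, events, risk) -> float:
    """Harrell's concordance of a risk score against right-censored times.

    A pair (i, j) is comparable when ``t_i < t_j`` and case i's event was
    observed; it is concordant when the earlier case has the higher risk
    score, and ties in risk count one half. Returns C in [0, 1]; 0.5 is
    chance level. Raises when no pair is comparable.
    """
    t, e = _as_time_event(times, events)
    r = np.asarray(risk, dtype=float)
    if r.shape != t.shape:
        raise ValueError("risk must match times in shape")
    comparable = (t[:, None] < t[None, :]) & e[:, None]
    n_comp = comparable.sum()
    if n_comp == 0:
        raise ValueError("no comparable pairs")
    diff = r[:, None] - r[None, :]
    concordant = np.sum(comparable & (diff > 0))
    tied = np.sum(comparable & (diff == 0))
    return float((concordant + 0.5 * tied) / n_comp)
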