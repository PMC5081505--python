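"""Bed-occupancy curves: expected and actual occupied beds over a day grid.

Given a group of patients currently in the unit, the occupancy at day ``t``
(t = 0 is the prediction morning) counts how many of them still occupy a bed.
Three constructions are provided:

* ``predict_occupancy_rsf`` — the survival-forest forecast: each patient
  contributes their survival probability ``S_i(t) = exp(-CHF_i(t))`` and the
  expected occupancy is the sum of these probabilities at each day.
* ``predict_occupancy_pointwise`` — the forecast implied by a point
  prediction of each patient's remaining stay (used by the RF regression and
  the sampling baseline): a patient with predicted remaining stay L occupies
  a bed on days 0 .. ceil(L)-1, i.e. ``curve(t) = #{i : L_i > t}``.
* ``real_occupancy`` — the ground truth from actual remaining stays to
  physical ICU exit (death frees a bed just as discharge does).

All curves live on the integer grid 0..horizon inclusive (horizon+1 points).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .survival_forest import SurvivalForestModel

__all__ = [
    "OccupancyCurve",
    "predict_occupancy_rsf",
    "predict_occupancy_pointwise",
    "real_occupancy",
]


@dataclass(frozen=True)
class OccupancyCurve:
    """Occupied beds (expected or actual) on the day grid 0..horizon."""

    days: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "days", np.asarray(self.days, dtype=int))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.days.shape != self.values.shape:
            raise ValueError("days and values must have equal length")
        if np.any(self.values < 0):
            raise ValueError("occupancy values must be >= 0")

    @property
    def horizon(self) -> int:
        return int(self.days[-1]) if len(self.days) else 0

    def __len__(self) -> int:
        return len(self.days)


def _day_grid(horizon: int) -> np.ndarray:
    if horizon < 0:
        raise ValueError("horizon must be >= 0")
    return np.arange(horizon + 1)


def predict_occupancy_rsf(
    model: SurvivalForestModel, group, horizon: int = 10
) -> OccupancyCurve:
    """Expected occupancy: sum of per-patient survival functions per day."""
    group = np.atleast_2d(np.asarray(group, dtype=float))
    if len(group) == 0:
        raise ValueError("group must be non-empty")
    days = _day_grid(horizon)
    surv = model.predict_survival_matrix(group, days.astype(float))
    return OccupancyCurve(days, surv.sum(axis=0))


def pointwise_curve_matrix(predicted_los, horizon: int) -> np.ndarray:
    """Per-patient 0/1 occupancy rows implied by point predictions."""
    pred = np.asarray(predicted_los, dtype=float).reshape(-1)
    if np.any(pred < 0):
        raise ValueError("predicted remaining stays must be >= 0")
    days = _day_grid(horizon)
    return (pred[:, None] > days[None, :]).astype(float)


def predict_occupancy_pointwise(predicted_los, horizon: int = 10) -> OccupancyCurve:
    """Occupancy implied by point predictions: ``curve(t) = #{i : L_i > t}``."""
    rows = pointwise_curve_matrix(predicted_los, horizon)
    return OccupancyCurve(_day_grid(horizon), rows.sum(axis=0))


def real_occupancy(actual_remaining, horizon: int = 10) -> OccupancyCurve:
    """Actual occupancy from remaining stays to physical ICU exit."""
    rows = pointwise_curve_matrix(actual_remaining, horizon)
    return OccupancyCurve(_day_grid(horizon), rows.sum(axis=0))
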