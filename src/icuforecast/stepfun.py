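"""Right-continuous step functions on a day grid.

Cumulative hazard and survival estimators in this package are step functions:
flat between knots, jumping at event times, evaluated right-continuously.
Before the first knot the function takes a ``baseline`` value (0 for a
cumulative hazard, 1 for a survival function).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["StepFunction"]


@dataclass(frozen=True)
class StepFunction:
    """A right-continuous step function.

    ``f(t) = baseline`` for ``t < x[0]`` and ``f(t) = y[i]`` for
    ``x[i] <= t < x[i+1]``. Knots must be strictly increasing.
    """

    x: np.ndarray
    y: np.ndarray
    baseline: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))
        if self.x.ndim != 1 or self.y.ndim != 1 or len(self.x) != len(self.y):
            raise ValueError("x and y must be 1-D arrays of equal length")
        if len(self.x) > 1 and not np.all(np.diff(self.x) > 0):
            raise ValueError("knots must be strictly increasing")

    def __call__(self, t) -> np.ndarray | float:
        t_arr = np.asarray(t, dtype=float)
        if len(self.x) == 0:
            out = np.full(t_arr.shape, self.baseline)
        else:
            idx = np.searchsorted(self.x, t_arr, side="right")
            out = np.where(idx > 0, self.y[np.maximum(idx - 1, 0)], self.baseline)
        if np.ndim(t) == 0:
            return float(out)
        return out

    @property
    def is_nondecreasing(self) -> bool:
        vals = np.concatenate(([self.baseline], self.y))
        return bool(np.all(np.diff(vals) >= 0))

    def scaled(self, factor: float) -> "StepFunction":
        return StepFunction(self.x, self.y * factor, self.baseline * factor)
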