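"""Right-continuous step functions, zero at time zero.

All estimators in this package (cumulative hazards, their variance
estimators, band limits) are piecewise-constant càdlàg functions that
start at 0.  :class:`StepFunction` is the shared carrier: it stores the
jump grid and the function values *at* the grid points; evaluation at an
arbitrary time returns the value at the largest grid time not exceeding
it (0 before the first grid time, the last value beyond the grid).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["StepFunction"]


@dataclass(frozen=True)
class StepFunction:
    """A right-continuous piecewise-constant function with f(0) = 0.

    Parameters
    ----------
    times : array-like
        Nondecreasing jump times, all strictly positive.
    values : array-like
        Function values at (and right of) each jump time.
    """

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or v.ndim != 1 or t.shape != v.shape:
            raise ValueError("times and values must be 1-d arrays of equal length")
        if t.size and np.any(np.diff(t) < 0):
            raise ValueError("times must be nondecreasing")
        if t.size and t[0] <= 0:
            raise ValueError("all jump times must be strictly positive (f(0) = 0)")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def __call__(self, t):
        """Evaluate at ``t`` (scalar or array), right-continuously."""
        t = np.asarray(t, dtype=float)
        if self.times.size == 0:
            out = np.zeros(t.shape)
            return out if out.ndim else 0.0
        idx = np.searchsorted(self.times, t, side="right") - 1
        out = np.where(idx >= 0, self.values[np.clip(idx, 0, None)], 0.0)
        return out if out.ndim else float(out)

    def restrict(self, t1: float, t2: float) -> "StepFunction":
        """Restriction to [t1, t2]: grid point at t1 carrying f(t1), then
        the interior jump times."""
        if t1 > t2:
            raise ValueError("t1 must not exceed t2")
        mask = (self.times > t1) & (self.times <= t2)
        if t1 <= 0:
            return StepFunction(self.times[mask], self.values[mask])
        times = np.concatenate([[t1], self.times[mask]])
        values = np.concatenate([[self(t1)], self.values[mask]])
        return StepFunction(times, values)

    @property
    def final_value(self) -> float:
        return float(self.values[-1]) if self.values.size else 0.0

    def to_frame(self) -> pd.DataFrame:
        """Two-column representation with the explicit (0, 0) first row."""
        return pd.DataFrame(
            {
                "time": np.concatenate([[0.0], self.times]),
                "value": np.concatenate([[0.0], self.values]),
            }
        )

    def to_csv(self, path, **kwargs) -> None:
        self.to_frame().to_csv(path, index=False, **kwargs)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "StepFunction":
        t = np.asarray(frame["time"], dtype=float)
        v = np.asarray(frame["value"], dtype=float)
        keep = t > 0
        return cls(t[keep], v[keep])

    @classmethod
    def from_csv(cls, path) -> "StepFunction":
        return cls.from_frame(pd.read_csv(path))

    @classmethod
    def constant(cls, value: float, at: float) -> "StepFunction":
        return cls(np.array([at]), np.array([value]))
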