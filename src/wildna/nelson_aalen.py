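"""Nelson–Aalen estimation under Aalen's multiplicative intensity model.

For a counting process N with intensity λ(t) = α(t)·Y(t) the cumulative
hazard A(t) = ∫₀ᵗ α is estimated by the Nelson–Aalen estimator

    Â(t) = Σ_{s ≤ t} J(s) ΔN(s) / Y(s),      J(s) = 1{Y(s) > 0},

with the convention 0/0 := 0.  Two variance estimators of the limit
covariance ψ(t, t) of √n(Â − A) are provided: the Aalen-type

    σ̂²(t) = n Σ_{s ≤ t} J(s) ΔN(s) / Y(s)²

and the Greenwood-type

    σ̂²(t) = n Σ_{s ≤ t} J(s) (Y(s) − ΔN(s)) ΔN(s) / Y(s)³,

the latter never exceeding the former.  All three are step functions on
the jump grid of the counting data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .event_data import CountingData, Records, TransitionKey, build_counting_data
from .stepfun import StepFunction

__all__ = [
    "NAFit",
    "nelson_aalen",
    "aalen_variance",
    "greenwood_variance",
    "fit_nelson_aalen",
    "NelsonAalenEstimator",
]


@dataclass(frozen=True)
class NAFit:
    """A fitted Nelson–Aalen estimate with both variance estimators,
    all sharing the jump grid of the underlying counting data."""

    transition: TransitionKey
    estimate: StepFunction
    var_aalen: StepFunction
    var_greenwood: StepFunction
    n: int
    tau: float
    counting_data: CountingData

    def variance(self, source: str = "aalen") -> StepFunction:
        if source == "aalen":
            return self.var_aalen
        if source == "greenwood":
            return self.var_greenwood
        raise ValueError(f"unknown variance source {source!r}")


def nelson_aalen(cd: CountingData) -> StepFunction:
    """Â(t) = Σ_{s ≤ t} ΔN(s)/Y(s) on the jump grid."""
    increments = cd.delta_n / cd.y_at_jumps.astype(float)
    return StepFunction(cd.jump_times, np.cumsum(increments))


def aalen_variance(cd: CountingData) -> StepFunction:
    """Aalen-type estimator n·Σ ΔN/Y² of the limit variance of √n(Â−A)."""
    y = cd.y_at_jumps.astype(float)
    increments = cd.n * cd.delta_n / y**2
    return StepFunction(cd.jump_times, np.cumsum(increments))


def greenwood_variance(cd: CountingData) -> StepFunction:
    """Greenwood-type estimator n·Σ (Y−ΔN)·ΔN/Y³."""
    y = cd.y_at_jumps.astype(float)
    increments = cd.n * (y - cd.delta_n) * cd.delta_n / y**3
    return StepFunction(cd.jump_times, np.cumsum(increments))


def fit_nelson_aalen(cd: CountingData) -> NAFit:
    """Estimate and both variances in one pass over the jump grid."""
    return NAFit(
        transition=cd.transition,
        estimate=nelson_aalen(cd),
        var_aalen=aalen_variance(cd),
        var_greenwood=greenwood_variance(cd),
        n=cd.n,
        tau=cd.tau,
        counting_data=cd,
    )


class NelsonAalenEstimator(BaseEstimator):
    """Nelson–Aalen estimator of one cumulative transition hazard.

    Scikit-learn-style estimator over multistate event-history records.

    Parameters
    ----------
    transition : tuple of (from_state, to_state)
        The transition whose cumulative hazard is estimated.
    tau : float, optional
        Observation horizon; defaults to the largest exit time.
    n : int, optional
        Sample-size-related normalizer of the variance estimators;
        defaults to the number of distinct subjects.
    censoring_precedes_events : bool, default False
        Flip the convention for event/censoring time ties.

    Attributes
    ----------
    cumulative_hazard_ : StepFunction
        The estimate Â on the jump grid.
    variance_aalen_, variance_greenwood_ : StepFunction
        The two variance estimators of √n(Â − A).
    counting_data_ : CountingData
    fit_ : NAFit

    Examples
    --------
    >>> import pandas as pd
    >>> X = pd.DataFrame({"id": ["a", "b", "c"], "entry": [0, 0, 0],
    ...                   "exit": [1.0, 2.0, 2.5], "from": ["0"] * 3,
    ...                   "to": ["2", "2", "cens"]})
    >>> est = NelsonAalenEstimator(transition=("0", "2"), tau=3.0).fit(X)
    >>> float(est.predict(2.0))  # 1/3 + 1/2
    0.8333333333333333
    """

    def __init__(
        self,
        transition=("0", "1"),
        tau: float | None = None,
        n: int | None = None,
        censoring_precedes_events: bool = False,
    ):
        self.transition = transition
        self.tau = tau
        self.n = n
        self.censoring_precedes_events = censoring_precedes_events

    def fit(self, X: Records, y=None) -> "NelsonAalenEstimator":
        from .event_data import as_frame

        frame = as_frame(X)
        tau = self.tau if self.tau is not None else float(frame["exit"].max())
        cd = build_counting_data(
            frame,
            TransitionKey(*self.transition),
            tau=tau,
            n=self.n,
            censoring_precedes_events=self.censoring_precedes_events,
        )
        self.counting_data_ = cd
        self.fit_ = fit_nelson_aalen(cd)
        self.cumulative_hazard_ = self.fit_.estimate
        self.variance_aalen_ = self.fit_.var_aalen
        self.variance_greenwood_ = self.fit_.var_greenwood
        self.n_ = cd.n
        self.tau_ = cd.tau
        return self

    def predict(self, T):
        """Evaluate the fitted cumulative hazard at times ``T``."""
        return self.cumulative_hazard_(np.asarray(T, dtype=float))
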