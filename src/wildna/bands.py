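"""Time-simultaneous confidence bands for cumulative hazards.

Two calibrations of the sup statistic are implemented.

*Brownian bridge* ("_a" bands): √n(Â − A)/(1 + σ̂²) · g(φ̂), with
φ̂ = σ̂²/(1 + σ̂²), converges to g·B⁰ time-transformed by φ, so the
critical value is a Monte-Carlo quantile of sup |g(s)B⁰(s)| over
[φ̂(t₁), φ̂(t₂)] for a standard Brownian bridge B⁰.

*Wild bootstrap* ("_w" bands): the same sup functional applied to the
bootstrap replicates Ŵ⁽ᵇ⁾, whose conditional law mimics √n(Â − A);
quantiles are order statistics across draws.

The weight g is either g₁(s) = (s(1−s))^{−1/2} (equal-precision bands,
equalizing pointwise coverage) or g₂ ≡ 1 (Hall–Wellner bands).  With
φ = σ²/(1+σ²) these weights simplify against the transform: the
weighted process is |·|/σ for g₁ and |·|/(1+σ²) for g₂.  Log-transformed
back-transformations give bands that cannot cross zero; the untransformed
direct band ("dir_w") is Â ∓ c̃/√n and may reach below zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.base import BaseEstimator

from .event_data import Records, TransitionKey, build_counting_data
from .nelson_aalen import NAFit, fit_nelson_aalen
from .stepfun import StepFunction
from .wild_bootstrap import (
    MultiplierSpec,
    WildBootstrapDraws,
    bootstrap_quantile,
    empirical_variance,
    wild_bootstrap_paths,
)

__all__ = [
    "BAND_TYPES",
    "BandSpec",
    "ConfidenceBand",
    "phi_hat",
    "bb_critical_value",
    "wb_critical_value",
    "build_band",
    "difference_band",
    "simultaneous_intervals",
    "sidak_region",
    "ConfidenceBandEstimator",
]

BAND_TYPES = ("EP_a", "HW_a", "EP_w", "HW_w", "dir_w")

#: guard against the unbounded g1 weight at the edges of [0, 1]
_G1_EDGE = 1e-3


@dataclass(frozen=True)
class BandSpec:
    """Configuration of one confidence band."""

    band_type: str = "HW_w"
    alpha: float = 0.05
    interval: tuple[float, float] | None = None
    variance_source: str | None = None  # aalen | greenwood | empirical_wb
    multiplier: MultiplierSpec = field(default_factory=MultiplierSpec)
    B: int = 1000
    bb_paths: int = 1000
    bb_grid: int = 1000

    def __post_init__(self):
        if self.band_type not in BAND_TYPES + ("diff_w",):
            raise ValueError(f"unknown band type {self.band_type!r}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.variance_source is None:
            # Greenwood gives more accurate Brownian-bridge coverage; the
            # across-draw empirical variance is the natural bootstrap choice.
            source = "greenwood" if self.band_type.endswith("_a") else "empirical_wb"
            object.__setattr__(self, "variance_source", source)

    @property
    def weight(self) -> str:
        if self.band_type.startswith("EP"):
            return "g1"
        if self.band_type.startswith("HW"):
            return "g2"
        return "identity"


@dataclass(frozen=True)
class ConfidenceBand:
    """Lower/upper band limits on the jump grid restricted to the interval."""

    lower: StepFunction
    upper: StepFunction
    critical_value: float
    spec: BandSpec
    estimate: StepFunction | None = None

    @property
    def times(self) -> np.ndarray:
        return self.lower.times

    def to_frame(self):
        import pandas as pd

        data = {"time": self.lower.times}
        if self.estimate is not None:
            data["estimate"] = self.estimate(self.lower.times)
        data["lower"] = self.lower.values
        data["upper"] = self.upper.values
        return pd.DataFrame(data)


def phi_hat(variance: StepFunction) -> StepFunction:
    """The time transform φ̂ = σ̂²/(1 + σ̂²), with values in [0, 1)."""
    if np.any(variance.values < 0):
        raise ValueError("variance must be nonnegative")
    return StepFunction(variance.times, variance.values / (1.0 + variance.values))


def _g_weight(g: str, s: np.ndarray) -> np.ndarray:
    if g == "g1":
        return 1.0 / np.sqrt(s * (1.0 - s))
    if g == "g2":
        return np.ones_like(s)
    raise ValueError(f"unknown weight id {g!r}")


def bb_critical_value(
    g: str,
    phi_lo: float,
    phi_hi: float,
    alpha: float,
    n_paths: int = 1000,
    grid: int = 1000,
    seed: int = 0,
) -> float:
    """Monte-Carlo (1−alpha) quantile of sup_{s∈[phi_lo,phi_hi]} |g(s)B⁰(s)|.

    Standard Brownian-bridge paths are simulated exactly on a uniform
    grid over [phi_lo, phi_hi] (B⁰(s) = W(s) − sW(1)).  Within each grid
    segment the conditional maximum and minimum of the path given its
    endpoints are additionally sampled in closed form (the reflection
    formula M = (a + b + √((a−b)² − 2·Δt·log U))/2 and its mirror
    image), so the sup carries no downward grid bias; the weight is
    taken as the larger endpoint value per segment.  A degenerate
    interval (phi_lo == phi_hi) reduces to the quantile of
    |g(φ)·N(0, φ(1−φ))|.
    """
    if not 0.0 <= phi_lo <= phi_hi < 1.0:
        raise ValueError("need 0 <= phi_lo <= phi_hi < 1")
    if g == "g1" and phi_lo <= 0.0:
        raise ValueError("g1 weight is unbounded at 0; need phi_lo > 0")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    s = np.linspace(phi_lo, phi_hi, grid) if phi_hi > phi_lo else np.array([phi_lo])
    w = _g_weight(g, s)
    dt = np.diff(np.concatenate([s, [1.0]]))
    rng = np.random.default_rng(seed)
    sups = np.empty(n_paths)
    chunk = max(1, min(n_paths, int(2**22 // max(1, s.size))))
    done = 0
    dt_seg = np.diff(s)
    w_seg = np.maximum(w[:-1], w[1:]) if s.size > 1 else None
    while done < n_paths:
        b = min(chunk, n_paths - done)
        incr = rng.standard_normal((b, s.size + 1))
        incr[:, 0] = np.sqrt(s[0]) * incr[:, 0] if s[0] > 0 else 0.0
        incr[:, 1:] *= np.sqrt(dt)
        wpath = np.cumsum(incr, axis=1)
        bridge = wpath[:, :-1] - np.outer(wpath[:, -1], s)
        if s.size == 1:
            sups[done : done + b] = np.abs(bridge * w).max(axis=1)
        else:
            a, bb = bridge[:, :-1], bridge[:, 1:]
            gap2 = (a - bb) ** 2
            hi = 0.5 * (a + bb + np.sqrt(gap2 - 2.0 * dt_seg * np.log(rng.random(a.shape))))
            lo = 0.5 * (a + bb - np.sqrt(gap2 - 2.0 * dt_seg * np.log(rng.random(a.shape))))
            sups[done : done + b] = (w_seg * np.maximum(hi, -lo)).max(axis=1)
        done += b
    return bootstrap_quantile(sups, alpha)


def _transformed_sups(
    draws: WildBootstrapDraws,
    g: str,
    variance: StepFunction | None,
    interval: tuple[float, float],
) -> np.ndarray:
    """Per-draw sup over the interval of the g-weighted transformed path.

    With φ = σ²/(1+σ²) the transform |Ŵ/(1+σ²)·g(φ)| simplifies to
    |Ŵ|/σ for g1 and |Ŵ|/(1+σ²) for g2; identity leaves |Ŵ|.
    """
    t1, t2 = interval
    if t1 > t2:
        raise ValueError("interval endpoints must satisfy t1 <= t2")
    grid = draws.jump_times
    eval_times = np.unique(
        np.concatenate([[t1], grid[(grid > t1) & (grid <= t2)]])
    )
    values = np.abs(draws.path_values_at(eval_times))
    if g == "identity":
        return values.max(axis=1) if values.size else np.zeros(draws.B)
    if variance is None:
        raise ValueError("g1/g2 transforms need a variance step function")
    sig2 = variance(eval_times)
    if g == "g1":
        if np.any(sig2 <= 0):
            raise ValueError(
                "g1 weight undefined where the variance is zero; move t1 "
                "right of the first event"
            )
        phi = sig2 / (1.0 + sig2)
        if phi[0] < _G1_EDGE or phi[-1] > 1.0 - _G1_EDGE:
            raise ValueError(
                "equal-precision transform too close to the edges of [0, 1]; "
                "shrink the interval"
            )
        values = values / np.sqrt(sig2)
    elif g == "g2":
        values = values / (1.0 + sig2)
    else:
        raise ValueError(f"unknown weight id {g!r}")
    return values.max(axis=1) if values.size else np.zeros(draws.B)


def wb_critical_value(
    draws: WildBootstrapDraws,
    g: str,
    variance: StepFunction | None,
    alpha: float,
    interval: tuple[float, float],
) -> float:
    """Wild-bootstrap critical value c̃: the (1−alpha) order-statistic
    quantile of the per-draw sup of the transformed path over the
    interval.  ``g`` is "g1", "g2", or "identity" (the direct band)."""
    return bootstrap_quantile(_transformed_sups(draws, g, variance, interval), alpha)


def build_band(
    fit: NAFit,
    critical_value: float,
    spec: BandSpec,
    variance: StepFunction | None = None,
) -> ConfidenceBand:
    """Back-transform a critical value into band limits on [t1, t2].

    EP:  Â·exp(∓ c·σ̂ / (√n·Â));  HW:  Â·exp(∓ c·(1+σ̂²) / (√n·Â));
    dir: Â ∓ c/√n.  The variance is taken from ``spec.variance_source``
    (pass ``variance`` explicitly for the empirical bootstrap variance).
    """
    if critical_value < 0:
        raise ValueError("critical value must be nonnegative")
    if spec.interval is None:
        raise ValueError("band spec needs an interval")
    t1, t2 = spec.interval
    est = fit.estimate.restrict(t1, t2)
    a_vals = est.values
    sqrt_n = np.sqrt(fit.n)
    if spec.band_type == "dir_w":
        lower = a_vals - critical_value / sqrt_n
        upper = a_vals + critical_value / sqrt_n
    else:
        if fit.estimate(t1) <= 0:
            raise ValueError(
                "transformed bands need Â(t1) > 0; move t1 right of the "
                "first observed event"
            )
        if spec.variance_source == "empirical_wb":
            if variance is None:
                raise ValueError(
                    "variance_source 'empirical_wb' requires the empirical "
                    "bootstrap variance to be passed in"
                )
            var_fn = variance
        else:
            var_fn = fit.variance(spec.variance_source)
        sig2 = var_fn(est.times)
        if spec.band_type.startswith("EP"):
            spread = critical_value * np.sqrt(sig2) / (sqrt_n * a_vals)
        else:  # Hall–Wellner
            spread = critical_value * (1.0 + sig2) / (sqrt_n * a_vals)
        lower = a_vals * np.exp(-spread)
        upper = a_vals * np.exp(spread)
    return ConfidenceBand(
        lower=StepFunction(est.times, lower),
        upper=StepFunction(est.times, upper),
        critical_value=float(critical_value),
        spec=spec,
        estimate=fit.estimate,
    )


def difference_band(
    fit1: NAFit,
    fit2: NAFit,
    draws1: WildBootstrapDraws,
    draws2: WildBootstrapDraws,
    alpha: float,
    interval: tuple[float, float],
    g=None,
) -> ConfidenceBand:
    """Within-sample band for A₁ − A₂: (Â₁ − Â₂) ∓ q̃/√n, where q̃ is the
    (1−alpha) bootstrap quantile of sup |g·(Ŵ₁⁽ᵇ⁾ − Ŵ₂⁽ᵇ⁾)| over the
    union jump grid in the interval (g ≡ 1 by default)."""
    if fit1.n != fit2.n:
        raise ValueError("difference bands require a shared sample size n")
    t1, t2 = interval
    grid = np.unique(np.concatenate([draws1.jump_times, draws2.jump_times]))
    eval_times = np.unique(np.concatenate([[t1], grid[(grid > t1) & (grid <= t2)]]))
    eval_times = eval_times[eval_times > 0]
    diff_paths = draws1.path_values_at(eval_times) - draws2.path_values_at(eval_times)
    if g is not None:
        w = g(eval_times) if callable(g) else np.asarray(g, dtype=float)
        diff_paths = diff_paths * w
    sups = (
        np.abs(diff_paths).max(axis=1) if eval_times.size else np.zeros(draws1.B)
    )
    q = bootstrap_quantile(sups, alpha)
    d_vals = fit1.estimate(eval_times) - fit2.estimate(eval_times)
    half = q / np.sqrt(fit1.n)
    spec = BandSpec(band_type="diff_w", alpha=alpha, interval=interval,
                    multiplier=draws1.multiplier, B=draws1.B)
    diff_est = StepFunction(eval_times, d_vals) if eval_times.size else StepFunction(
        np.array([]), np.array([])
    )
    return ConfidenceBand(
        lower=StepFunction(eval_times, d_vals - half),
        upper=StepFunction(eval_times, d_vals + half),
        critical_value=q,
        spec=spec,
        estimate=diff_est,
    )


def simultaneous_intervals(
    fit: NAFit,
    draws: WildBootstrapDraws,
    timepoints,
    alpha: float,
    band_type: str = "HW_w",
    variance: StepFunction | None = None,
):
    """Simultaneous confidence intervals at a finite set of time points:
    the max over the set replaces the sup in the critical value, then the
    band formulas are applied pointwise.  Returns a DataFrame with one
    row per time point."""
    import pandas as pd

    timepoints = np.sort(np.asarray(timepoints, dtype=float))
    if timepoints.size == 0:
        raise ValueError("need at least one time point")
    if np.any(timepoints <= 0) or np.any(timepoints > fit.tau):
        raise ValueError("time points must lie in (0, tau]")
    if variance is None and band_type != "dir_w":
        variance = empirical_variance(draws)
    values = np.abs(draws.path_values_at(timepoints))
    if band_type == "dir_w":
        maxima = values.max(axis=1)
    else:
        sig2 = variance(timepoints)
        if band_type.startswith("EP"):
            if np.any(sig2 <= 0):
                raise ValueError("equal-precision intervals need variance > 0")
            maxima = (values / np.sqrt(sig2)).max(axis=1)
        else:
            maxima = (values / (1.0 + sig2)).max(axis=1)
    c = bootstrap_quantile(maxima, alpha)
    rows = []
    sqrt_n = np.sqrt(fit.n)
    for s in timepoints:
        a = fit.estimate(s)
        if band_type == "dir_w":
            lo, hi = a - c / sqrt_n, a + c / sqrt_n
        else:
            if a <= 0:
                raise ValueError(f"transformed interval needs Â({s}) > 0")
            v = variance(s)
            spread = (
                c * np.sqrt(v) / (sqrt_n * a)
                if band_type.startswith("EP")
                else c * (1.0 + v) / (sqrt_n * a)
            )
            lo, hi = a * np.exp(-spread), a * np.exp(spread)
        rows.append((s, a, lo, hi))
    out = pd.DataFrame(rows, columns=["time", "estimate", "lower", "upper"])
    out.attrs["critical_value"] = c
    return out


def sidak_region(
    fits,
    draws,
    t: float,
    alpha: float,
    band_type: str = "HW_w",
):
    """Šidák product region for (A₁(t), …, A_k(t)): each component is a
    pointwise interval at level (1−alpha)^{1/k}.  Returns a DataFrame
    with one row per component."""
    import pandas as pd

    fits = list(fits)
    draws = list(draws)
    if len(fits) != len(draws) or not fits:
        raise ValueError("need matching, nonempty fit and draw collections")
    k = len(fits)
    alpha_comp = 1.0 - (1.0 - alpha) ** (1.0 / k)
    rows = []
    for f, d in zip(fits, draws):
        iv = simultaneous_intervals(f, d, [t], alpha_comp, band_type=band_type)
        rows.append(
            (str(f.transition), t, iv["estimate"][0], iv["lower"][0], iv["upper"][0])
        )
    out = pd.DataFrame(rows, columns=["transition", "time", "estimate", "lower", "upper"])
    out.attrs["component_level"] = 1.0 - alpha_comp
    return out


class ConfidenceBandEstimator(BaseEstimator):
    """Simultaneous confidence band for one cumulative transition hazard.

    Parameters mirror :class:`BandSpec`; ``fit`` accepts event-history
    records (DataFrame with columns ``id, entry, exit, from, to`` or an
    iterable of :class:`~wildna.event_data.EventRecord`).

    Attributes
    ----------
    band_ : ConfidenceBand
    critical_value_ : float
    na_fit_ : NAFit
    draws_ : WildBootstrapDraws or None
        Present for the wild-bootstrap calibrations.
    """

    def __init__(
        self,
        transition=("0", "1"),
        band_type: str = "HW_w",
        alpha: float = 0.05,
        interval: tuple[float, float] | None = None,
        variance_source: str | None = None,
        multiplier: str = "standard_normal",
        B: int = 1000,
        bb_paths: int = 1000,
        bb_grid: int = 1000,
        random_state: int = 0,
        tau: float | None = None,
        n: int | None = None,
    ):
        self.transition = transition
        self.band_type = band_type
        self.alpha = alpha
        self.interval = interval
        self.variance_source = variance_source
        self.multiplier = multiplier
        self.B = B
        self.bb_paths = bb_paths
        self.bb_grid = bb_grid
        self.random_state = random_state
        self.tau = tau
        self.n = n

    def fit(self, X: Records, y=None) -> "ConfidenceBandEstimator":
        from .event_data import as_frame

        frame = as_frame(X)
        tau = self.tau if self.tau is not None else float(frame["exit"].max())
        cd = build_counting_data(frame, TransitionKey(*self.transition), tau=tau, n=self.n)
        na = fit_nelson_aalen(cd)
        interval = self.interval
        if interval is None:
            if cd.num_jumps == 0:
                raise ValueError("no observed events; cannot build a band")
            interval = (float(cd.jump_times[0]), tau)
        mult = MultiplierSpec(self.multiplier, self.random_state)
        spec = BandSpec(
            band_type=self.band_type,
            alpha=self.alpha,
            interval=interval,
            variance_source=self.variance_source,
            multiplier=mult,
            B=self.B,
            bb_paths=self.bb_paths,
            bb_grid=self.bb_grid,
        )
        variance = None
        self.draws_ = None
        if spec.band_type.endswith("_a"):
            var_fn = na.variance(spec.variance_source)
            phi = phi_hat(var_fn)
            c = bb_critical_value(
                spec.weight,
                float(phi(interval[0])),
                float(phi(interval[1])),
                spec.alpha,
                n_paths=spec.bb_paths,
                grid=spec.bb_grid,
                seed=self.random_state,
            )
        else:
            self.draws_ = wild_bootstrap_paths(cd, mult, spec.B)
            if spec.band_type != "dir_w":
                variance = (
                    empirical_variance(self.draws_)
                    if spec.variance_source == "empirical_wb"
                    else na.variance(spec.variance_source)
                )
            c = wb_critical_value(self.draws_, spec.weight, variance, spec.alpha, interval)
        self.na_fit_ = na
        self.critical_value_ = c
        self.band_ = build_band(na, c, spec, variance=variance)
        return self

    def predict(self, T):
        """Band limits at times ``T``: array of shape (len(T), 2)."""
        T = np.asarray(T, dtype=float)
        return np.column_stack([self.band_.lower(T), self.band_.upper(T)])
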