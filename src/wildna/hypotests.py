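"""Resampling tests for cumulative hazards.

Three families of tests, all calibrated by the wild bootstrap:

* Kolmogorov–Smirnov-type *equality* tests of two cumulative hazards,
  within one sample (two transitions of the same multistate process) or
  across two independent samples.
* An *equivalence* test by confidence-band inclusion: non-equivalence to
  a reference hazard A₀ within margins (ℓ, u) is rejected when the
  combined one-sided bands lie strictly inside (A₀ − ℓ, A₀ + u).
* A two-sample *proportional hazards* test: under H₀: A⁽¹⁾ = c·A⁽²⁾ the
  weighted distance between Â⁽²⁾/Â⁽¹⁾ and its value at τ converges to a
  resampleable limit; both sup-norm (KS) and integrated-square (CvM)
  distances are available, with weight w = Â⁽¹⁾.

Decisions use the Monte-Carlo-test order statistic min(B, ⌈(1−α)(B+1)⌉)
as critical value; together with the add-one p-value
(1 + #{draws ≥ statistic})/(B + 1) this makes "reject" equivalent to
"p ≤ α" whenever the bootstrap draws are tie-free and B ≥ 1/α − 1.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Union

import numpy as np
from sklearn.base import BaseEstimator

from .event_data import CountingData, Records, TransitionKey, as_frame, build_counting_data
from .nelson_aalen import NAFit, fit_nelson_aalen, nelson_aalen
from .stepfun import StepFunction
from .wild_bootstrap import (
    MultiplierSpec,
    WildBootstrapDraws,
    mc_test_critical_value,
    wild_bootstrap_paths,
)

__all__ = [
    "TestResult",
    "EquivalenceMargins",
    "derive_seed",
    "ks_equality_test",
    "ks_two_sample_equality_test",
    "equivalence_test",
    "proportionality_test",
    "WithinSampleEqualityTest",
    "TwoSampleEqualityTest",
    "TwoSampleProportionalityTest",
]


def derive_seed(seed: int, *key: int) -> int:
    """Deterministically derive an independent sub-seed (< 2³¹)."""
    return int(np.random.SeedSequence(seed, spawn_key=key).generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class TestResult:
    """Outcome of one resampling test."""

    name: str
    statistic: float
    critical_value: float
    p_value: float | None
    reject: bool
    alpha: float
    B: int | None = None
    interval: tuple[float, float] | None = None
    multiplier: str | None = None
    seed: int | None = None

    def to_record(self) -> dict:
        return {
            "test": self.name,
            "statistic": self.statistic,
            "critical_value": self.critical_value,
            "p_value": self.p_value,
            "reject": self.reject,
            "alpha": self.alpha,
            "B": self.B,
            "interval": list(self.interval) if self.interval else None,
            "multiplier": self.multiplier,
            "seed": self.seed,
        }


def _finish(name, statistic, sups, alpha, B, interval, spec) -> TestResult:
    critical = mc_test_critical_value(sups, alpha)
    p = (1.0 + np.sum(sups >= statistic)) / (B + 1.0)
    return TestResult(
        name=name,
        statistic=float(statistic),
        critical_value=float(critical),
        p_value=float(p),
        reject=bool(statistic > critical),
        alpha=alpha,
        B=B,
        interval=interval,
        multiplier=spec.family if spec is not None else None,
        seed=spec.seed if spec is not None else None,
    )


def _union_eval_times(interval, *grids):
    t1, t2 = interval
    grid = np.concatenate([g for g in grids if g.size] or [np.array([])])
    inner = grid[(grid > t1) & (grid <= t2)]
    return np.unique(np.concatenate([[t1], inner])) if t1 > 0 else np.unique(
        np.concatenate([[0.0], inner])
    )


def _weights(g, times):
    if g is None:
        return 1.0
    return g(times) if callable(g) else np.asarray(g, dtype=float)


def ks_equality_test(
    fit1: NAFit,
    fit2: NAFit,
    draws1: WildBootstrapDraws,
    draws2: WildBootstrapDraws,
    g=None,
    alpha: float = 0.05,
    interval: tuple[float, float] | None = None,
) -> TestResult:
    """Within-sample KS test of H₀: A₁ ≡ A₂ on [t₁, t₂].

    Statistic √n·sup g·|Â₁ − Â₂|; the null distribution is approximated
    by sup |g·(Ŵ₁⁽ᵇ⁾ − Ŵ₂⁽ᵇ⁾)| across draws (the two bootstrap streams
    must be independent).
    """
    if fit1.n != fit2.n:
        raise ValueError("within-sample comparison requires a shared n")
    if interval is None:
        interval = (0.0, min(fit1.tau, fit2.tau))
    times = _union_eval_times(interval, fit1.estimate.times, fit2.estimate.times)
    w = _weights(g, times)
    diff = fit1.estimate(times) - fit2.estimate(times)
    statistic = np.sqrt(fit1.n) * np.max(np.abs(w * diff)) if times.size else 0.0
    boot = draws1.path_values_at(times) - draws2.path_values_at(times)
    sups = np.max(np.abs(boot * w), axis=1) if times.size else np.zeros(draws1.B)
    return _finish(
        "ks_equality", statistic, sups, alpha, draws1.B, interval, draws1.multiplier
    )


def ks_two_sample_equality_test(
    cd1: CountingData,
    cd2: CountingData,
    g=None,
    alpha: float = 0.05,
    interval: tuple[float, float] | None = None,
    B: int = 1000,
    spec: MultiplierSpec | None = None,
) -> TestResult:
    """Two-sample KS test of H₀: A⁽¹⁾ ≡ A⁽²⁾ for independent samples of
    sizes n₁, n₂, with the rate √(n₁n₂/n) and bootstrap process
    √(n₁/n)·Ŵ⁽²⁾ − √(n₂/n)·Ŵ⁽¹⁾."""
    spec = spec or MultiplierSpec()
    n1, n2 = cd1.n, cd2.n
    n = n1 + n2
    if interval is None:
        interval = (0.0, min(cd1.tau, cd2.tau))
    na1, na2 = nelson_aalen(cd1), nelson_aalen(cd2)
    times = _union_eval_times(interval, na1.times, na2.times)
    w = _weights(g, times)
    factor = np.sqrt(n1 * n2 / n)
    statistic = (
        factor * np.max(np.abs(w * (na1(times) - na2(times)))) if times.size else 0.0
    )
    draws1 = wild_bootstrap_paths(cd1, replace(spec, seed=derive_seed(spec.seed, 1)), B)
    draws2 = wild_bootstrap_paths(cd2, replace(spec, seed=derive_seed(spec.seed, 2)), B)
    boot = np.sqrt(n1 / n) * draws2.path_values_at(times) - np.sqrt(
        n2 / n
    ) * draws1.path_values_at(times)
    sups = np.max(np.abs(boot * w), axis=1) if times.size else np.zeros(B)
    return _finish("ks_two_sample_equality", statistic, sups, alpha, B, interval, spec)


@dataclass(frozen=True)
class EquivalenceMargins:
    """Reference hazard A₀ with strictly positive margin functions ℓ, u
    on the testing interval.  ``ell`` and ``u`` may be constants,
    callables, or step functions."""

    A0: StepFunction
    ell: Union[float, Callable, StepFunction] = 1.0
    u: Union[float, Callable, StepFunction] = 1.0

    def _eval(self, which, times):
        m = self.ell if which == "ell" else self.u
        if callable(m):
            vals = np.asarray(m(times), dtype=float)
        else:
            vals = np.full(len(times), float(m))
        if np.any(vals <= 0):
            raise ValueError("equivalence margins must be strictly positive")
        return vals


def equivalence_test(
    one_sided_lower: StepFunction,
    one_sided_upper: StepFunction,
    margins: EquivalenceMargins,
    interval: tuple[float, float],
    alpha: float = 0.05,
) -> TestResult:
    """Equivalence by band inclusion: reject non-equivalence iff
    a_n(s) > A₀(s) − ℓ(s) and b_n(s) < A₀(s) + u(s) for every s in the
    interval (strict inequalities).  The statistic is the largest margin
    violation, so rejection corresponds to a negative statistic."""
    t1, t2 = interval
    times = _union_eval_times(
        interval, one_sided_lower.times, one_sided_upper.times, margins.A0.times
    )
    times = np.unique(np.append(times, [t1, t2]))
    times = times[(times >= t1) & (times <= t2)]
    a = one_sided_lower(times)
    b = one_sided_upper(times)
    a0 = margins.A0(times)
    ell = margins._eval("ell", times)
    u = margins._eval("u", times)
    violation = np.maximum((a0 - ell) - a, b - (a0 + u))
    statistic = float(np.max(violation))
    return TestResult(
        name="equivalence_inclusion",
        statistic=statistic,
        critical_value=0.0,
        p_value=None,
        reject=bool(statistic < 0.0),
        alpha=alpha,
        interval=interval,
    )


def _proportionality_raw(
    cd1: CountingData,
    cd2: CountingData,
    tau: float,
    B: int,
    spec: MultiplierSpec,
):
    """Statistic and bootstrap sup/integral values for both distances.

    Returns dict with 'KS'/'CvM' statistics and B-vectors of bootstrap
    values.  Evaluation runs over pooled jump times in (0, τ] from the
    first jump of sample 1 onward (where the weight w = Â⁽¹⁾ > 0).
    """
    if cd1.num_jumps == 0 or cd1.jump_times[0] > tau:
        raise ValueError("sample 1 has no events on (0, tau]; Â⁽¹⁾ ≡ 0 there")
    n1, n2 = cd1.n, cd2.n
    n = n1 + n2
    na1, na2 = nelson_aalen(cd1), nelson_aalen(cd2)
    pooled = np.unique(np.concatenate([cd1.jump_times, cd2.jump_times]))
    pooled = pooled[(pooled <= tau) & (pooled >= cd1.jump_times[0])]
    a1 = na1(pooled)
    a2 = na2(pooled)
    a1_tau, a2_tau = na1(tau), na2(tau)
    ratio_tau = a2_tau / a1_tau
    factor = np.sqrt(n1 * n2 / n)
    # segment widths for the exact piecewise-constant CvM integral on [·, τ]
    dt = np.diff(np.append(pooled, tau))
    diff = a2 - a1 * ratio_tau  # = w·(f − g)/factor
    ks_stat = factor * np.max(np.abs(diff))
    cvm_stat = factor**2 * float(np.sum(diff**2 * dt))

    draws1 = wild_bootstrap_paths(cd1, replace(spec, seed=derive_seed(spec.seed, 1)), B)
    draws2 = wild_bootstrap_paths(cd2, replace(spec, seed=derive_seed(spec.seed, 2)), B)
    w1 = draws1.path_values_at(pooled)
    w2 = draws2.path_values_at(pooled)
    w1_tau = draws1.path_values_at([tau])[:, 0]
    w2_tau = draws2.path_values_at([tau])[:, 0]
    r1, r2 = np.sqrt(n1 / n), np.sqrt(n2 / n)
    z = r1 * w2 / a1 - r2 * w1 * a2 / a1**2
    z_tau = r1 * w2_tau / a1_tau - r2 * w1_tau * a2_tau / a1_tau**2
    dev = a1 * (z - z_tau[:, None])  # weight w = Â⁽¹⁾ applied to (Ẑ − Ẑ(τ))
    ks_boot = np.max(np.abs(dev), axis=1)
    cvm_boot = np.sum(dev**2 * dt, axis=1)
    return {
        "KS": (float(ks_stat), ks_boot),
        "CvM": (float(cvm_stat), cvm_boot),
    }


def proportionality_test(
    cd1: CountingData,
    cd2: CountingData,
    rho: str = "KS",
    alpha: float = 0.05,
    B: int = 1000,
    tau: float | None = None,
    spec: MultiplierSpec | None = None,
) -> TestResult:
    """Two-sample test of H₀: A⁽¹⁾ = c·A⁽²⁾ on [0, τ] for some c > 0.

    ``rho`` selects the distance: "KS" (sup-norm) or "CvM" (integrated
    square), both weighted by w = Â⁽¹⁾.
    """
    spec = spec or MultiplierSpec()
    rho_key = {"ks": "KS", "cvm": "CvM"}.get(str(rho).lower())
    if rho_key is None:
        raise ValueError(f"unknown distance {rho!r}; use 'KS' or 'CvM'")
    if tau is None:
        tau = min(cd1.tau, cd2.tau)
    statistic, boot = _proportionality_raw(cd1, cd2, tau, B, spec)[rho_key]
    return _finish(
        f"proportionality_{rho_key.lower()}", statistic, boot, alpha, B, (0.0, tau), spec
    )


# ---------------------------------------------------------------------------
# sklearn-style surfaces


def _split_two_samples(X, y):
    frame = as_frame(X)
    y = np.asarray(y)
    if len(y) != len(frame):
        raise ValueError("y must assign one group label per record row")
    labels = np.unique(y)
    if labels.size != 2:
        raise ValueError(f"need exactly two group labels, got {labels!r}")
    return frame[y == labels[0]], frame[y == labels[1]], labels


class WithinSampleEqualityTest(BaseEstimator):
    """KS test of equality of two transition hazards of one sample.

    ``fit(X)`` takes event-history records; the two hazards compared are
    named by ``transitions``.
    """

    def __init__(
        self,
        transitions=(("0", "1"), ("0", "2")),
        g=None,
        alpha: float = 0.05,
        interval: tuple[float, float] | None = None,
        B: int = 1000,
        multiplier: str = "standard_normal",
        random_state: int = 0,
        tau: float | None = None,
        n: int | None = None,
    ):
        self.transitions = transitions
        self.g = g
        self.alpha = alpha
        self.interval = interval
        self.B = B
        self.multiplier = multiplier
        self.random_state = random_state
        self.tau = tau
        self.n = n

    def fit(self, X: Records, y=None) -> "WithinSampleEqualityTest":
        frame = as_frame(X)
        tau = self.tau if self.tau is not None else float(frame["exit"].max())
        fits, draws = [], []
        for k, tr in enumerate(self.transitions):
            cd = build_counting_data(frame, TransitionKey(*tr), tau=tau, n=self.n)
            fits.append(fit_nelson_aalen(cd))
            spec = MultiplierSpec(self.multiplier, derive_seed(self.random_state, k))
            draws.append(wild_bootstrap_paths(cd, spec, self.B))
        self.result_ = ks_equality_test(
            fits[0], fits[1], draws[0], draws[1], self.g, self.alpha, self.interval
        )
        self.statistic_ = self.result_.statistic
        self.critical_value_ = self.result_.critical_value
        self.p_value_ = self.result_.p_value
        self.reject_ = self.result_.reject
        return self


class TwoSampleEqualityTest(BaseEstimator):
    """KS test of equality of one transition hazard across two samples.

    ``fit(X, y)`` takes pooled records plus a per-row group label.
    """

    def __init__(
        self,
        transition=("0", "1"),
        g=None,
        alpha: float = 0.05,
        interval: tuple[float, float] | None = None,
        B: int = 1000,
        multiplier: str = "standard_normal",
        random_state: int = 0,
        tau: float | None = None,
    ):
        self.transition = transition
        self.g = g
        self.alpha = alpha
        self.interval = interval
        self.B = B
        self.multiplier = multiplier
        self.random_state = random_state
        self.tau = tau

    def fit(self, X: Records, y=None) -> "TwoSampleEqualityTest":
        f1, f2, self.groups_ = _split_two_samples(X, y)
        tau = self.tau
        if tau is None:
            tau = float(min(f1["exit"].max(), f2["exit"].max()))
        key = TransitionKey(*self.transition)
        cd1 = build_counting_data(f1, key, tau=tau)
        cd2 = build_counting_data(f2, key, tau=tau)
        self.result_ = ks_two_sample_equality_test(
            cd1,
            cd2,
            self.g,
            self.alpha,
            self.interval,
            self.B,
            MultiplierSpec(self.multiplier, self.random_state),
        )
        self.statistic_ = self.result_.statistic
        self.critical_value_ = self.result_.critical_value
        self.p_value_ = self.result_.p_value
        self.reject_ = self.result_.reject
        return self


class TwoSampleProportionalityTest(BaseEstimator):
    """Wild-bootstrap test of proportional hazards across two samples.

    ``fit(X, y)`` takes pooled event-history records plus a per-row
    group label; ``rho`` is "KS" or "CvM".
    """

    def __init__(
        self,
        transition=("0", "1"),
        rho: str = "KS",
        alpha: float = 0.05,
        B: int = 1000,
        tau: float | None = None,
        multiplier: str = "standard_normal",
        random_state: int = 0,
    ):
        self.transition = transition
        self.rho = rho
        self.alpha = alpha
        self.B = B
        self.tau = tau
        self.multiplier = multiplier
        self.random_state = random_state

    def fit(self, X: Records, y=None) -> "TwoSampleProportionalityTest":
        f1, f2, self.groups_ = _split_two_samples(X, y)
        tau = self.tau
        if tau is None:
            tau = float(min(f1["exit"].max(), f2["exit"].max()))
        key = TransitionKey(*self.transition)
        cd1 = build_counting_data(f1, key, tau=tau)
        cd2 = build_counting_data(f2, key, tau=tau)
        self.result_ = proportionality_test(
            cd1,
            cd2,
            rho=self.rho,
            alpha=self.alpha,
            B=self.B,
            tau=tau,
            spec=MultiplierSpec(self.multiplier, self.random_state),
        )
        self.statistic_ = self.result_.statistic
        self.critical_value_ = self.result_.critical_value
        self.p_value_ = self.result_.p_value
        self.reject_ = self.result_.reject
        return self
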