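"""Wild-bootstrap replicates of the normalized Nelson–Aalen process.

The normalized estimator W_n = √n(Â − A) is resampled by keeping the
data fixed and weighting every unit jump of the counting process with an
independent mean-0/variance-1 multiplier G:

    Ŵ(t) = √n Σ_{unit events e ≤ t} G_e / Y(e).

One multiplier is consumed per unit event — a tied jump of size ΔN
consumes ΔN i.i.d. multipliers — never one per subject: time-constant
per-subject weights fail to reproduce the independent-increment
covariance structure.  Conditionally on the data, Ŵ is a mean-zero
square-integrable martingale whose predictable variation is the
Aalen-type variance estimator; its optional variation

    σ*²(t) = n Σ_{e ≤ t} G_e² / Y(e)²

is the bootstrap analogue of the variance and is materialized per draw.

Two multiplier families are built in: standard normal and centered
Poisson(1) (skewness one, which can improve second-order accuracy).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

from .event_data import CountingData, TransitionKey
from .stepfun import StepFunction

__all__ = [
    "MULTIPLIER_FAMILIES",
    "MultiplierSpec",
    "WildBootstrapDraws",
    "draw_multipliers",
    "paths_from_multipliers",
    "wild_bootstrap_paths",
    "empirical_variance",
    "sup_statistics",
    "bootstrap_quantile",
    "mc_test_critical_value",
]

MULTIPLIER_FAMILIES = ("standard_normal", "centered_poisson1")

_ALIASES = {
    "normal": "standard_normal",
    "gaussian": "standard_normal",
    "standard_normal": "standard_normal",
    "poisson": "centered_poisson1",
    "centered_poisson": "centered_poisson1",
    "centered_poisson1": "centered_poisson1",
}


@dataclass(frozen=True)
class MultiplierSpec:
    """White-noise multiplier family plus the root seed.

    The root seed deterministically derives independent streams per
    transition (keyed by the transition label), so multi-transition runs
    are reproducible and order-independent.
    """

    family: str = "standard_normal"
    seed: int = 0

    def __post_init__(self):
        family = _ALIASES.get(str(self.family))
        if family is None:
            raise ValueError(
                f"unknown multiplier family {self.family!r}; "
                f"choose from {MULTIPLIER_FAMILIES}"
            )
        object.__setattr__(self, "family", family)

    def rng(self, *, transition: TransitionKey | None = None) -> np.random.Generator:
        if transition is None:
            key = ()
        else:
            key = (zlib.crc32(str(transition).encode()),)
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=key))


def _sample(family: str, rng: np.random.Generator, shape) -> np.ndarray:
    if family == "standard_normal":
        return rng.standard_normal(shape)
    # centered Poisson(1): mean 0, variance 1, skewness 1
    return rng.poisson(1.0, shape).astype(float) - 1.0


def draw_multipliers(
    spec: MultiplierSpec,
    num_events: int,
    B: int,
    *,
    transition: TransitionKey | None = None,
) -> np.ndarray:
    """A B × num_events table of i.i.d. multipliers (one row per draw)."""
    if num_events < 0:
        raise ValueError("num_events must be >= 0")
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = spec.rng(transition=transition)
    return _sample(spec.family, rng, (B, num_events))


@dataclass(frozen=True)
class WildBootstrapDraws:
    """B wild-bootstrap paths Ŵ⁽ᵇ⁾ evaluated on the jump grid, plus the
    per-draw optional-variation processes σ*²⁽ᵇ⁾."""

    transition: TransitionKey
    jump_times: np.ndarray
    paths: np.ndarray  # shape (B, num jump times)
    star_var: np.ndarray  # shape (B, num jump times)
    n: int
    B: int
    multiplier: MultiplierSpec

    def path_values_at(self, times) -> np.ndarray:
        """Evaluate every path right-continuously at the given times
        (shape (B, len(times)); 0 before the first jump)."""
        times = np.asarray(times, dtype=float)
        if self.jump_times.size == 0:
            return np.zeros((self.B, times.size))
        idx = np.searchsorted(self.jump_times, times, side="right") - 1
        out = np.where(idx >= 0, self.paths[:, np.clip(idx, 0, None)], 0.0)
        return out


def paths_from_multipliers(cd: CountingData, G: np.ndarray):
    """Ŵ and σ*² paths on the jump grid from an explicit multiplier table.

    ``G`` has one column per *unit* event (a tied jump of size ΔN owns
    ΔN consecutive columns).  Returns the pair of (B, num jumps) arrays.
    """
    G = np.atleast_2d(np.asarray(G, dtype=float))
    units = int(cd.delta_n.sum())
    if G.shape[1] != units:
        raise ValueError(f"need one multiplier per unit event ({units}), got {G.shape[1]}")
    if cd.num_jumps == 0:
        return np.zeros((G.shape[0], 0)), np.zeros((G.shape[0], 0))
    inv_y_units = np.repeat(1.0 / cd.y_at_jumps.astype(float), cd.delta_n)
    # index of the last unit event belonging to each (possibly tied) jump
    last = np.cumsum(cd.delta_n) - 1
    paths = np.sqrt(cd.n) * np.cumsum(G * inv_y_units, axis=1)[:, last]
    star = cd.n * np.cumsum((G * inv_y_units) ** 2, axis=1)[:, last]
    return paths, star


def wild_bootstrap_paths(
    cd: CountingData, spec: MultiplierSpec, B: int
) -> WildBootstrapDraws:
    """Generate B replicate paths of Ŵ and σ*² on the jump grid of ``cd``.

    A tied jump of size ΔN consumes ΔN independent multipliers, so the
    construction is identical to the one obtained by breaking every tie
    into unit jumps.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    G = draw_multipliers(spec, int(cd.delta_n.sum()), B, transition=cd.transition)
    paths, star = paths_from_multipliers(cd, G)
    return WildBootstrapDraws(cd.transition, cd.jump_times, paths, star, cd.n, B, spec)


def empirical_variance(draws: WildBootstrapDraws, *, center: bool = False) -> StepFunction:
    """Across-draw variance of Ŵ at each jump time.

    The conditional mean of Ŵ is exactly zero, so by default the
    uncentered second moment is used; ``center=True`` switches to the
    mean-centered version.
    """
    if draws.B < 2:
        raise ValueError("empirical_variance needs B >= 2 draws")
    if center:
        values = np.var(draws.paths, axis=0)
    else:
        values = np.mean(draws.paths**2, axis=0)
    return StepFunction(draws.jump_times, values)


def sup_statistics(
    draws: WildBootstrapDraws,
    weight=None,
    interval: tuple[float, float] | None = None,
) -> np.ndarray:
    """Per draw, sup over jump times in [t1, t2] of |weight(s) · Ŵ(s)|.

    ``weight`` may be None (≡ 1), a StepFunction, a callable, or an
    array aligned with the jump grid.  The sup over an empty grid is 0.
    """
    t = draws.jump_times
    if interval is None:
        mask = np.ones(t.shape, dtype=bool)
    else:
        t1, t2 = interval
        if t1 > t2:
            raise ValueError("interval endpoints must satisfy t1 <= t2")
        mask = (t >= t1) & (t <= t2)
    if not mask.any():
        return np.zeros(draws.B)
    values = np.abs(draws.paths[:, mask])
    if weight is not None:
        w = weight(t[mask]) if callable(weight) else np.asarray(weight, dtype=float)[mask]
        values = values * np.abs(w)
    return values.max(axis=1)


def bootstrap_quantile(values, alpha: float) -> float:
    """The ⌈(1−alpha)·B⌉-th order statistic of ``values``."""
    values = np.sort(np.asarray(values, dtype=float))
    if values.size == 0:
        raise ValueError("cannot take a quantile of an empty collection")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    m = int(np.ceil((1.0 - alpha) * values.size))
    return float(values[m - 1])


def mc_test_critical_value(values, alpha: float) -> float:
    """Monte-Carlo-test critical value: the min(B, ⌈(1−alpha)(B+1)⌉)-th
    order statistic, which makes 'statistic > critical value' equivalent
    to the add-one p-value being ≤ alpha (absent ties)."""
    values = np.sort(np.asarray(values, dtype=float))
    if values.size == 0:
        raise ValueError("cannot take a quantile of an empty collection")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    m = min(values.size, int(np.ceil((1.0 - alpha) * (values.size + 1))))
    return float(values[m - 1])
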