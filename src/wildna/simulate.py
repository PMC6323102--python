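"""Synthetic data generators and Monte-Carlo operating-characteristics studies.

Two generators are provided.

* A two-group competing-risks model with constant cause-specific hazards
  (α₀₁, α₀₂ per group) and administrative censoring at the group-specific
  time c solving exp(−(α₀₁+α₀₂)·c) = censoring fraction.  Four named
  scenarios (I–IV) cover no/moderate/large group effects on the type-1
  hazard with the competing hazard fixed at 2; they drive the type-I-error
  study of the proportional-hazards test (τ = 0.3, ≈25% censored).

* An illness-death-with-recovery model (states 0 healthy, 1 ill,
  2 absorbing; transitions 0→1, 1→0, 0→2, 1→2) driven by a synthetic
  discrete increment template: event times live on a finite grid and are
  drawn sojourn by sojourn as a nested series of competing-risks
  experiments whose discrete hazards are the template increments, so the
  true cumulative hazards are the running sums of the increments and
  coverage is exactly computable.  The template is a synthetic stand-in
  for templates derived from real cohort data.

The harnesses :func:`run_size_study` and :func:`run_coverage_study`
replicate whole studies (simulate → estimate → resample → decide) and
report rejection rates / coverage fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .bands import BandSpec, build_band, wb_critical_value
from .event_data import CENSORED, CountingData, TransitionKey, build_counting_data
from .nelson_aalen import fit_nelson_aalen
from .stepfun import StepFunction
from .wild_bootstrap import (
    MultiplierSpec,
    empirical_variance,
    mc_test_critical_value,
    wild_bootstrap_paths,
)
from .hypotests import _proportionality_raw, derive_seed

__all__ = [
    "CompetingRisksScenario",
    "SCENARIO_HAZARDS",
    "scenario",
    "censoring_time_for_fraction",
    "simulate_two_sample_competing_risks",
    "ConstantHazardSurvival",
    "MultistateTemplate",
    "make_synthetic_template",
    "simulate_multistate_from_template",
    "band_covers",
    "run_size_study",
    "run_coverage_study",
    "run_equality_size_study",
]

#: (α01, α02) per group for the four named constant-hazard scenarios.
SCENARIO_HAZARDS = {
    "I": ((2.0, 2.0), (2.0, 2.0)),
    "II": ((1.0, 2.0), (2.0, 2.0)),
    "III": ((1.0, 2.0), (1.0, 2.0)),
    "IV": ((1.0, 2.0), (1.5, 2.0)),
}


@dataclass(frozen=True)
class CompetingRisksScenario:
    """Two-group competing-risks design with constant hazards."""

    hazards_group1: tuple[float, float]
    hazards_group2: tuple[float, float]
    n_per_group: int = 125
    tau: float = 0.3
    censoring_fraction: float = 0.25
    seed: int = 0
    label: str = ""

    def __post_init__(self):
        for h in (*self.hazards_group1, *self.hazards_group2):
            if h <= 0:
                raise ValueError("hazards must be positive")
        if not 0 < self.censoring_fraction < 1:
            raise ValueError("censoring fraction must lie in (0, 1)")


def scenario(name: str, n_per_group: int = 125, **kwargs) -> CompetingRisksScenario:
    """One of the named scenarios I–IV."""
    key = str(name).upper()
    if key not in SCENARIO_HAZARDS:
        raise ValueError(f"unknown scenario {name!r}; choose from {list(SCENARIO_HAZARDS)}")
    h1, h2 = SCENARIO_HAZARDS[key]
    return CompetingRisksScenario(
        hazards_group1=h1, hazards_group2=h2, n_per_group=n_per_group, label=key, **kwargs
    )


def censoring_time_for_fraction(total_hazard: float, fraction: float) -> float:
    """Administrative censoring time c with exp(−total_hazard·c) = fraction,
    i.e. the time by which the target fraction is still event-free."""
    if total_hazard <= 0:
        raise ValueError("total hazard must be positive")
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie strictly in (0, 1)")
    return -np.log(fraction) / total_hazard


def _simulate_group(rng, n, hazards, censor_time):
    a1, a2 = hazards
    lam = a1 + a2
    t = rng.exponential(1.0 / lam, n)
    cause = np.where(rng.random(n) < a1 / lam, 1, 2)
    censored = t > censor_time
    exit_ = np.where(censored, censor_time, t)
    return exit_, np.where(censored, 0, cause)


def _group_frame(exit_, cause, prefix):
    to = np.where(cause == 0, CENSORED, cause.astype(str))
    return pd.DataFrame(
        {
            "id": [f"{prefix}{i}" for i in range(len(exit_))],
            "entry": 0.0,
            "exit": exit_,
            "from": "0",
            "to": to,
        }
    )


def simulate_two_sample_competing_risks(
    sc: CompetingRisksScenario,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Event-history records for both groups.

    Per subject: event time ~ Exp(α₀₁+α₀₂), cause 1 with probability
    α₀₁/(α₀₁+α₀₂), administratively censored at the group-specific time
    from :func:`censoring_time_for_fraction`.
    """
    rng = np.random.default_rng(sc.seed)
    frames = []
    for prefix, hz in (("g1_", sc.hazards_group1), ("g2_", sc.hazards_group2)):
        c = censoring_time_for_fraction(sum(hz), sc.censoring_fraction)
        exit_, cause = _simulate_group(rng, sc.n_per_group, hz, c)
        frames.append(_group_frame(exit_, cause, prefix))
    return frames[0], frames[1]


def _counting_from_exits(exit_, cause, which_cause, tau, n, transition):
    """CountingData for one cause directly from exit-time arrays (all
    subjects enter at 0, so Y(s) = n − #{exits < s})."""
    ev = np.sort(exit_[(cause == which_cause) & (exit_ <= tau)])
    jump_times, delta = np.unique(ev, return_counts=True)
    exits_sorted = np.sort(exit_)
    y = len(exit_) - np.searchsorted(exits_sorted, jump_times, side="left")
    return CountingData(
        transition=transition,
        jump_times=jump_times,
        delta_n=delta,
        y_at_jumps=y,
        n=n,
        tau=tau,
    )


# ---------------------------------------------------------------------------
# one-transition constant-hazard survival generator (coverage studies)


@dataclass(frozen=True)
class ConstantHazardSurvival:
    """n subjects, a single 0→1 transition with constant hazard, optional
    administrative censoring; A(t) = hazard·t."""

    hazard: float = 1.0
    n: int = 200
    tau: float = 1.0
    censor_time: float | None = None

    def sample_counting_data(self, rng) -> CountingData:
        t = rng.exponential(1.0 / self.hazard, self.n)
        if self.censor_time is not None:
            cause = np.where(t > self.censor_time, 0, 1)
            exit_ = np.minimum(t, self.censor_time)
        else:
            cause = np.ones(self.n, dtype=int)
            exit_ = t
        return _counting_from_exits(
            exit_, cause, 1, self.tau, self.n, TransitionKey("0", "1")
        )

    def true_cumhaz(self):
        h = self.hazard
        return lambda t: h * np.asarray(t, dtype=float)


# ---------------------------------------------------------------------------
# illness-death-with-recovery template machinery


@dataclass(frozen=True)
class MultistateTemplate:
    """Discrete-time multistate simulation template.

    ``increments[(l, m)]`` maps a transition to the vector of discrete
    hazards ΔA_lm on the shared ``grid`` (the conditional probability of
    an l→m jump at that grid time given occupancy of l just before it);
    the total exit hazard Σ_m ΔA_lm must not exceed 1 anywhere.
    ``censoring`` holds probability masses on the grid (plus one mass at
    'beyond the grid', appended as the last entry) and must sum to 1, as
    must ``initial_distribution`` over the states.
    """

    states: tuple[str, ...]
    absorbing: tuple[str, ...]
    grid: np.ndarray
    increments: dict
    censoring: np.ndarray
    initial_distribution: dict

    def __post_init__(self):
        g = np.asarray(self.grid, dtype=float)
        if np.any(g <= 0) or np.any(np.diff(g) <= 0):
            raise ValueError("grid times must be positive and increasing")
        object.__setattr__(self, "grid", g)
        cens = np.asarray(self.censoring, dtype=float)
        if cens.size != g.size + 1 or not np.isclose(cens.sum(), 1.0):
            raise ValueError("censoring masses must sum to 1 over grid + beyond")
        object.__setattr__(self, "censoring", cens)
        if not np.isclose(sum(self.initial_distribution.values()), 1.0):
            raise ValueError("initial distribution must sum to 1")
        for a in self.absorbing:
            if any(l == a for (l, _) in self.increments):
                raise ValueError(f"absorbing state {a!r} has outgoing increments")
        by_state = {}
        for (l, _), inc in self.increments.items():
            by_state[l] = by_state.get(l, 0.0) + np.asarray(inc, dtype=float)
        for l, tot in by_state.items():
            if np.any(tot > 1.0):
                raise ValueError(f"total discrete hazard out of state {l!r} must be <= 1")

    @property
    def tau(self) -> float:
        return float(self.grid[-1])

    def transitions(self):
        return [TransitionKey(l, m) for (l, m) in self.increments]

    def true_cumhaz(self, transition: TransitionKey) -> StepFunction:
        inc = np.asarray(self.increments[(transition.from_state, transition.to_state)])
        return StepFunction(self.grid, np.cumsum(inc))


def make_synthetic_template(
    config: dict | None = None, seed: int = 0
) -> MultistateTemplate:
    """A reproducible synthetic illness-death-with-recovery template.

    Discrete hazards are sampled around smooth parametric shapes (an
    early-peaked recovery hazard, slowly increasing death hazards) and
    jittered by the seed; censoring mass decays geometrically across the
    grid with 20% of subjects never censored on it.
    """
    cfg = {
        "grid_size": 50,
        "tau": 30.0,
        "initial_ill": 0.25,
        "scale": {"01": 0.030, "10": 0.045, "02": 0.055, "12": 0.035},
    }
    if config:
        cfg.update(config)
    rng = np.random.default_rng(seed)
    k = int(cfg["grid_size"])
    grid = np.linspace(cfg["tau"] / k, cfg["tau"], k)
    u = grid / cfg["tau"]
    shapes = {
        ("0", "1"): np.exp(-2.0 * u),
        ("1", "0"): np.exp(-1.0 * u),
        ("0", "2"): 0.5 + u,
        ("1", "2"): 0.4 + 0.8 * u,
    }
    increments = {}
    for (l, m), shape in shapes.items():
        scale = cfg["scale"][f"{l}{m}"]
        jitter = rng.uniform(0.7, 1.3, k)
        increments[(l, m)] = scale * shape * jitter
    cens = np.exp(-2.5 * u)
    cens = 0.8 * cens / cens.sum()
    censoring = np.append(cens, 0.2)
    return MultistateTemplate(
        states=("0", "1", "2"),
        absorbing=("2",),
        grid=grid,
        increments=increments,
        censoring=censoring,
        initial_distribution={"0": 1.0 - cfg["initial_ill"], "1": cfg["initial_ill"]},
    )


def simulate_multistate_from_template(
    template: MultistateTemplate, n: int, seed: int = 0
) -> pd.DataFrame:
    """Simulate n subjects sojourn by sojourn on the template grid.

    Initial states and censoring times are multinomial; within each
    sojourn the next event is a competing-risks experiment over the
    outgoing discrete hazards at each grid time given the current state
    and time only, so the process is Markov by construction.
    """
    rng = np.random.default_rng(seed)
    grid = template.grid
    k = grid.size
    states = list(template.initial_distribution)
    init_p = np.array([template.initial_distribution[s] for s in states])
    init_idx = rng.choice(len(states), size=n, p=init_p)
    cens_idx = rng.choice(k + 1, size=n, p=template.censoring)
    # per transient state: outgoing destination labels + (k, d) hazard matrix
    outgoing = {}
    for (l, m), inc in template.increments.items():
        outgoing.setdefault(l, ([], []))
        outgoing[l][0].append(m)
        outgoing[l][1].append(np.asarray(inc))
    hazard_total = {
        l: np.sum(np.column_stack(incs), axis=1) for l, (dests, incs) in outgoing.items()
    }
    rows = []
    for i in range(n):
        state = states[init_idx[i]]
        cens_time = grid[cens_idx[i]] if cens_idx[i] < k else np.inf
        pos = 0  # next grid index at which an event may occur
        entry = 0.0
        while state not in template.absorbing and pos < k:
            dests, incs = outgoing[state]
            total = hazard_total[state]
            u_ev = rng.random(k - pos)
            hits = np.nonzero(u_ev < total[pos:])[0]
            event_idx = pos + hits[0] if hits.size else k
            event_time = grid[event_idx] if event_idx < k else np.inf
            if cens_time < event_time:
                if cens_time > entry:
                    rows.append((f"s{i}", entry, cens_time, state, CENSORED))
                break
            if event_idx >= k:
                # observation ends administratively at the grid horizon
                if grid[-1] > entry:
                    rows.append((f"s{i}", entry, grid[-1], state, CENSORED))
                break
            p = np.array([inc[event_idx] for inc in incs])
            dest = dests[rng.choice(len(dests), p=p / p.sum())]
            rows.append((f"s{i}", entry, event_time, state, dest))
            state = dest
            entry = event_time
            pos = event_idx + 1
    return pd.DataFrame(rows, columns=["id", "entry", "exit", "from", "to"])


# ---------------------------------------------------------------------------
# Monte-Carlo harnesses


def run_size_study(
    sc: CompetingRisksScenario,
    n_studies: int = 1000,
    B: int = 1000,
    alpha: float = 0.05,
    rho="KS",
    spec: MultiplierSpec | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Empirical rejection rate of the proportional-hazards test.

    Each study simulates both groups, builds the type-1 counting
    processes on (0, τ], and applies the test with B bootstrap draws.
    ``rho`` may be "KS", "CvM", or a sequence of both (the bootstrap
    draws are shared across distances within a study).  Returns a tidy
    one-row-per-distance table.
    """
    spec = spec or MultiplierSpec()
    seed = sc.seed if seed is None else seed
    rhos = [rho] if isinstance(rho, str) else list(rho)
    keys = []
    for r in rhos:
        k = {"ks": "KS", "cvm": "CvM"}.get(str(r).lower())
        if k is None:
            raise ValueError(f"unknown distance {r!r}")
        keys.append(k)
    c1 = censoring_time_for_fraction(sum(sc.hazards_group1), sc.censoring_fraction)
    c2 = censoring_time_for_fraction(sum(sc.hazards_group2), sc.censoring_fraction)
    key = TransitionKey("0", "1")
    rejections = {k: 0 for k in keys}
    degenerate = 0
    for study in range(n_studies):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(study,)))
        e1, cse1 = _simulate_group(rng, sc.n_per_group, sc.hazards_group1, c1)
        e2, cse2 = _simulate_group(rng, sc.n_per_group, sc.hazards_group2, c2)
        cd1 = _counting_from_exits(e1, cse1, 1, sc.tau, sc.n_per_group, key)
        cd2 = _counting_from_exits(e2, cse2, 1, sc.tau, sc.n_per_group, key)
        if cd1.num_jumps == 0:
            degenerate += 1
            continue
        mspec = replace(spec, seed=derive_seed(seed, study, 0x5151))
        raw = _proportionality_raw(cd1, cd2, sc.tau, B, mspec)
        for k in keys:
            stat, boot = raw[k]
            if stat > mc_test_critical_value(boot, alpha):
                rejections[k] += 1
    rows = [
        {
            "scenario": sc.label or "custom",
            "n_per_group": sc.n_per_group,
            "rho": k,
            "multiplier": spec.family,
            "alpha": alpha,
            "n_studies": n_studies,
            "B": B,
            "rejection_rate": rejections[k] / max(1, n_studies),
            "n_degenerate": degenerate,
        }
        for k in keys
    ]
    return pd.DataFrame(rows)


def run_equality_size_study(
    kind: str = "within",
    n: int = 200,
    hazard: float = 1.0,
    tau: float = 1.0,
    n_studies: int = 1000,
    B: int = 500,
    alpha: float = 0.05,
    multiplier: str = "standard_normal",
    seed: int = 0,
    censor_time: float | None = None,
) -> float:
    """Null rejection rate of the KS equality tests under matched
    constant hazards.

    ``kind="within"``: one sample of ``n`` subjects with two competing
    transitions 0→1, 0→2, both with the given hazard, testing
    A₀₁ ≡ A₀₂.  ``kind="two_sample"``: two independent samples of ``n``
    subjects with a single 0→1 transition of the given hazard, testing
    A⁽¹⁾ ≡ A⁽²⁾.  Optional shared administrative censoring at
    ``censor_time``.
    """
    from .hypotests import ks_equality_test, ks_two_sample_equality_test

    if kind not in ("within", "two_sample"):
        raise ValueError("kind must be 'within' or 'two_sample'")
    key1, key2 = TransitionKey("0", "1"), TransitionKey("0", "2")
    rejections = 0
    for study in range(n_studies):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(study,)))
        if kind == "within":
            t = rng.exponential(0.5 / hazard, n)  # total exit hazard 2·hazard
            cause = np.where(rng.random(n) < 0.5, 1, 2)
            if censor_time is not None:
                cause = np.where(t > censor_time, 0, cause)
                t = np.minimum(t, censor_time)
            cd1 = _counting_from_exits(t, cause, 1, tau, n, key1)
            cd2 = _counting_from_exits(t, cause, 2, tau, n, key2)
            f1, f2 = fit_nelson_aalen(cd1), fit_nelson_aalen(cd2)
            d1 = wild_bootstrap_paths(
                cd1, MultiplierSpec(multiplier, derive_seed(seed, study, 1)), B
            )
            d2 = wild_bootstrap_paths(
                cd2, MultiplierSpec(multiplier, derive_seed(seed, study, 2)), B
            )
            res = ks_equality_test(f1, f2, d1, d2, alpha=alpha, interval=(0.0, tau))
        else:
            samples = []
            for _ in range(2):
                t = rng.exponential(1.0 / hazard, n)
                cause = np.ones(n, dtype=int)
                if censor_time is not None:
                    cause = np.where(t > censor_time, 0, cause)
                    t = np.minimum(t, censor_time)
                samples.append(_counting_from_exits(t, cause, 1, tau, n, key1))
            res = ks_two_sample_equality_test(
                samples[0],
                samples[1],
                alpha=alpha,
                interval=(0.0, tau),
                B=B,
                spec=MultiplierSpec(multiplier, derive_seed(seed, study, 3)),
            )
        rejections += res.reject
    return rejections / n_studies


def band_covers(lower, upper, truth, t1, t2, truth_times=None) -> bool:
    """Whether [lower, upper] contains the nondecreasing function
    ``truth`` on all of [t1, t2].

    For step-valued truth pass its jump times; for continuous truth the
    left-limit check at each band segment boundary uses the value at the
    right endpoint (exact by continuity and monotonicity).
    """
    pts = np.unique(
        np.concatenate(
            [
                [t1, t2],
                lower.times[(lower.times > t1) & (lower.times < t2)],
                [] if truth_times is None else np.asarray(truth_times)[
                    (np.asarray(truth_times) > t1) & (np.asarray(truth_times) < t2)
                ],
            ]
        )
    )
    tv = np.asarray(truth(pts), dtype=float)
    lo = lower(pts)
    hi = upper(pts)
    if np.any(lo > tv) or np.any(hi < tv):
        return False
    if truth_times is None:
        # continuous increasing truth: sup over [p_i, p_{i+1}) is truth(p_{i+1})
        if np.any(hi[:-1] < tv[1:]):
            return False
    return True


def _wb_bands_one_study(cd, band_types, alpha, interval, mspec, B):
    na = fit_nelson_aalen(cd)
    draws = wild_bootstrap_paths(cd, mspec, B)
    var_emp = empirical_variance(draws)
    out = {}
    for bt in band_types:
        spec = BandSpec(band_type=bt, alpha=alpha, interval=interval, B=B,
                        multiplier=mspec)
        weight = spec.weight
        c = wb_critical_value(draws, weight, var_emp, alpha, interval)
        out[bt] = build_band(na, c, spec, variance=var_emp)
    return na, var_emp, out


def run_coverage_study(
    generator,
    band_types=("EP_w", "HW_w"),
    n_studies: int = 1000,
    B: int = 1000,
    alpha: float = 0.05,
    interval: tuple[float, float] | None = None,
    multiplier: str = "standard_normal",
    seed: int = 0,
    transitions=None,
    include_pointwise: bool = False,
    min_expected_events: int = 20,
) -> pd.DataFrame:
    """Empirical simultaneous coverage of wild-bootstrap bands.

    ``generator`` is a :class:`ConstantHazardSurvival` (closed-form true
    hazard) or a :class:`MultistateTemplate` (true hazard = running sum
    of increments).  ``include_pointwise`` adds the diagnostic row
    "pointwise_log": the fraction of studies in which *all* log-
    transformed 95% pointwise intervals cover — the (wrong) simultaneous
    reading of pointwise intervals.
    """
    from scipy.stats import norm

    results = {}
    events = {}
    if isinstance(generator, MultistateTemplate):
        trans = transitions or [(t.from_state, t.to_state) for t in generator.transitions()]
        tau = generator.tau
    else:
        trans = [("0", "1")]
        tau = generator.tau
    if interval is None:
        interval = (0.0, tau)
    t1, t2 = interval
    z = norm.ppf(1.0 - alpha / 2.0)
    for study in range(n_studies):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(study,)))
        if isinstance(generator, MultistateTemplate):
            frame = simulate_multistate_from_template(
                generator, n=_template_n(generator), seed=derive_seed(seed, study, 1)
            )
        else:
            frame = None
        for tr in trans:
            key = TransitionKey(*tr)
            if isinstance(generator, MultistateTemplate):
                cd = build_counting_data(frame, key, tau=tau)
                truth = generator.true_cumhaz(key)
                truth_fn, truth_times = truth, truth.times
            else:
                cd = generator.sample_counting_data(rng)
                truth_fn, truth_times = generator.true_cumhaz(), None
            events[tr] = events.get(tr, 0) + cd.num_events
            mspec = MultiplierSpec(multiplier, derive_seed(seed, study, 2))
            na, var_emp, bands = _wb_bands_one_study(cd, band_types, alpha, interval, mspec, B)
            for bt, band in bands.items():
                covered = band_covers(band.lower, band.upper, truth_fn, t1, t2, truth_times)
                results[(tr, bt)] = results.get((tr, bt), 0) + covered
            if include_pointwise:
                times = cd.jump_times[(cd.jump_times >= t1) & (cd.jump_times <= t2)]
                a = na.estimate(times)
                sig = np.sqrt(na.var_aalen(times))
                spread = z * sig / (np.sqrt(cd.n) * a)
                lo, hi = a * np.exp(-spread), a * np.exp(spread)
                tv = np.asarray(truth_fn(times), dtype=float)
                ok = bool(np.all((lo <= tv) & (tv <= hi)))
                results[(tr, "pointwise_log")] = results.get((tr, "pointwise_log"), 0) + ok
    rows = []
    for (tr, bt), count in sorted(results.items()):
        mean_ev = events[tr] / n_studies
        rows.append(
            {
                "transition": f"{tr[0]}->{tr[1]}",
                "band_type": bt,
                "coverage": count / n_studies,
                "n_studies": n_studies,
                "B": B,
                "alpha": alpha,
                "mean_events": mean_ev,
                "low_events_flag": mean_ev < min_expected_events,
            }
        )
    return pd.DataFrame(rows)


def _template_n(template: MultistateTemplate, default: int = 200) -> int:
    return default
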