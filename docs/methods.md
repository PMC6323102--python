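# Methods

## Model and estimators

All procedures assume Aalen's multiplicative intensity model: each
counting process N_j of interest has intensity λ_j(t) = α_j(t)·Y_j(t)
with a deterministic hazard α_j and a predictable at-risk process Y_j.
This covers Markovian multistate models with finite state space
(Y_ℓ = number of subjects in state ℓ just before t), competing risks,
relative/excess mortality models (where Y is a generalized exposure and
the normalizer n need not be a subject count — it is therefore a caller
option), and independent right-censoring/left-truncation.  Observation
is restricted to a horizon [0, τ].

A subject is at risk at time s iff entry < s ≤ exit (left-open,
right-closed), so Y(s) is the count *just prior to* s and late entrants
(left truncation) join the risk set only after their entry time.  When
an event and a censoring share a time, the censored subject is counted
at risk for that event — events precede censorings, the standard
convention; `censoring_precedes_events=True` flips it, since the
convention is not forced by the theory.  Tied event times within one
transition are allowed (ΔN > 1) and treated as ΔN unit jumps; because Y
is constant within the tie this leaves the estimator unchanged and
fixes the bootstrap semantics (below).  Times are compared exactly; no
binning.

Estimators on the jump grid (0/0 := 0 throughout):

* Nelson–Aalen:  Â(t) = Σ_{s≤t} ΔN/Y — nonnegative, nondecreasing,
  càdlàg, 0 at 0;
* Aalen-type variance:  σ̂²(t) = n Σ ΔN/Y²;
* Greenwood-type variance:  σ̂²(t) = n Σ (Y−ΔN)ΔN/Y³ ≤ Aalen-type
  pointwise.

## The wild bootstrap

The law of W_n = √n(Â − A) on [0, τ] is approximated conditionally on
the data by

    Ŵ(t) = √n Σ_{unit events e ≤ t} G_e / Y(e),

with i.i.d. multipliers G_e, E G = 0, Var G = 1.  The construction
attaches **one multiplier per unit event**: a tied jump of size ΔN
consumes ΔN independent multipliers, and a subject experiencing several
transitions contributes several independent multipliers.  A single
time-constant multiplier per subject produces the wrong covariance
structure (the limit loses independent increments), which is why that
scheme is deliberately not offered.  Only multiplier values at event
times are materialized — the white-noise process never needs to be
simulated on a continuum because Ŵ integrates against dN.

Conditionally on the data, Ŵ is a mean-zero square-integrable
martingale; its predictable variation is the Aalen-type σ̂², and its
optional variation σ*²(t) = n Σ G²/Y² is carried per draw.  The test
suite checks these identities empirically (mean of σ*² across draws
against σ̂² within 3 Monte-Carlo standard errors at B = 10⁴; conditional
mean of Ŵ within 4σ̂/√B of zero; vanishing increment–start covariance)
and checks that the across-draw variance tracks the limit covariance
ψ(t,t) = ∫ α/y in a constant-hazard model.

Two multiplier families are built in: standard normal, and centered
Poisson(1), whose skewness of one can improve second-order accuracy.
Other mean-0/variance-1 families can be added by the user at their own
risk (moment conditions beyond the second are not checked).

Seeding: a root seed plus a stable per-transition key (CRC-32 of the
transition label) derives independent, order-independent streams, so a
multi-transition analysis is reproducible regardless of the order in
which transitions are processed.  Where two streams are needed on the
*same* transition label (two-sample procedures), sub-seeds are derived
through `derive_seed` (SeedSequence spawn keys, kept below 2³¹).

The across-draw "empirical variance" of Ŵ uses the uncentered second
moment, because the conditional mean is exactly zero by construction;
`center=True` switches to the centered version.

## Confidence bands

Weight functions: g₁(s) = (s(1−s))^{−1/2} (equal precision) and g₂ ≡ 1
(Hall–Wellner).  With φ = σ²/(1+σ²), the weighted transform of a
process X simplifies to |X|/σ for g₁ and |X|/(1+σ²) for g₂; sups are
evaluated **exactly** at the jump times inside [t₁, t₂] plus t₁ itself
(all processes are constant between jumps), never on an auxiliary grid.

Brownian-bridge calibration: the critical value is the Monte-Carlo
(1−α) quantile of sup_{s∈[φ̂(t₁), φ̂(t₂)]} |g(s)B⁰(s)|.  Bridge paths are
simulated exactly at grid points (default 1000 paths on a 1000-point
uniform grid; both configurable), and the within-segment maximum and
minimum of the bridge given its endpoints are additionally drawn in
closed form (reflection formula), removing the downward bias a plain
grid maximum would carry — the 95% quantile for g₂ on [0, 1] reproduces
the Kolmogorov-distribution point 1.3581 to Monte-Carlo accuracy.  The
two segment extremes are drawn independently given the endpoints, a
negligible approximation on fine grids.  Degenerate intervals reduce to
the normal quantile (0.98 for g₂ at φ = 0.5; 1.96 for g₁ at any φ).

Wild-bootstrap calibration replaces the Brownian bridge by the draws of
Ŵ transformed the same way; the direct band uses sup |Ŵ| untransformed.

Band shapes on [t₁, t₂] at critical value c:

* equal precision:  Â·exp(∓ c·σ̂ / (√n·Â));
* Hall–Wellner:     Â·exp(∓ c·(1+σ̂²) / (√n·Â));
* direct:           Â ∓ c/√n  (may reach below zero).

The log-transformed bands require Â(t₁) > 0 and are unstable for very
small Â(t₁); the implementation refuses them otherwise with guidance to
move t₁ right of the first event, and guards the g₁ weight by requiring
φ̂ ∈ [10⁻³, 1−10⁻³] on the interval (the weight is unbounded at the
edges; the threshold is an implementation choice).  Default variance
source: Greenwood for Brownian-bridge calibration (more accurate
coverage), the across-draw empirical bootstrap variance for
wild-bootstrap calibration; both overridable.

Difference bands for A₁ − A₂ (within one sample, shared n) use the
(1−α) quantile of sup |Ŵ₁ − Ŵ₂| over the union jump grid, by the
independence of the limit components; an optional weight g is applied
to both the band and the bootstrap sup.  Simultaneous intervals over a
finite time set replace the sup by a max over the set; Šidák regions
across k transitions use per-component level (1−α)^{1/k}.

## Hypothesis tests

*Equality (KS type).*  Within-sample: statistic √n·sup g|Â₁ − Â₂|,
calibrated by sup |g(Ŵ₁ − Ŵ₂)|.  Two-sample (independent samples,
n = n₁ + n₂): rate √(n₁n₂/n) and bootstrap process
√(n₁/n)·Ŵ⁽²⁾ − √(n₂/n)·Ŵ⁽¹⁾ (sign-symmetric).

*Equivalence by band inclusion.*  Given a reference A₀ and strictly
positive margins ℓ, u, non-equivalence is rejected iff the combined
one-sided bands lie strictly inside (A₀−ℓ, A₀+u) on the whole interval;
the reported statistic is the largest margin violation (negative iff
rejecting).  Each one-sided band is taken at level 1−α
(intersection–union logic; the construction reuses the symmetric
two-sided critical values, an approximation for the genuinely one-sided
problem).  No resampling p-value exists for this decision rule, so
`p_value` is None.

*Proportionality.*  H₀: A⁽¹⁾ = c·A⁽²⁾ on [0, τ].  Statistic
T = ρ(√(n₁n₂/n)·Â⁽²⁾/Â⁽¹⁾, √(n₁n₂/n)·Â⁽²⁾(τ)/Â⁽¹⁾(τ)) with weight
w = Â⁽¹⁾, which confines evaluation to {Â⁽¹⁾ > 0}; ρ is the sup-norm
(KS) or the integrated squared difference (CvM), the latter integrated
**exactly** as a sum of constant segments between pooled jump times up
to τ — no quadrature.  Times before the first jump of sample 1 are
excluded (w = 0 annihilates them for KS; for CvM the exclusion is
exact).  The bootstrap analogue applies the delta method:
√(n₁/n)·Ŵ⁽²⁾/Â⁽¹⁾ − √(n₂/n)·Ŵ⁽¹⁾·Â⁽²⁾/(Â⁽¹⁾)², compared against its
value at τ under the same ρ.

*Decision rule.*  All resampling tests report the add-one p-value
(1 + #{draws ≥ statistic})/(B + 1) — never exactly zero — and use the
min(B, ⌈(1−α)(B+1)⌉)-th order statistic of the bootstrap draws as
critical value, which makes "statistic > critical value" exactly
equivalent to p ≤ α whenever the draws are tie-free and B ≥ 1/α − 1.
The general-purpose `bootstrap_quantile` used by the confidence bands
keeps the conservative ⌈(1−α)B⌉ order statistic.

## Synthetic data generators

*Two-group competing risks (constant hazards).*  Scenarios I–IV fix the
type-1 hazards per group at (2,2), (1,2), (1,1), (1,1.5) with the
competing hazard 2 everywhere.  Event time ~ Exp(α₀₁+α₀₂), cause 1 with
probability α₀₁/(α₀₁+α₀₂).  The "approximately 25% censored" condition
is realized by the simplest mechanism consistent with it: a
group-specific administrative censoring time c solving
exp(−(α₀₁+α₀₂)·c) = 0.25, applied per group.  When c exceeds the
analysis horizon τ = 0.3 (true in all four scenarios) censoring occurs
after the window; records still carry it at c and analysis truncates at
τ.  The exact censoring mechanism behind the reference sizes is not
fully determined by "approximately 25%", so small discrepancies in their
reproduction can trace to this choice.

*Illness–death with recovery (synthetic template).*  States {0, 1, 2},
transitions 0→1, 1→0, 0→2, 1→2, state 2 absorbing.  The generator is
discrete: a template stores, on a finite time grid, the conditional
transition probabilities ΔA_lm(t_k) given occupancy of l just before
t_k, censoring masses over the grid (plus a never-censored-on-grid
mass), and an initial state distribution.  Simulation proceeds sojourn
by sojourn as a nested series of competing-risks experiments depending
only on the current state and time — Markov by construction; subjects
never censored on the grid are administratively censored at the grid
horizon.  The true cumulative hazards are exactly the running sums of
the ΔA_lm, making coverage computable without approximation.
`make_synthetic_template` emits a reproducible synthetic template
(50-point grid on (0, 30], early-peaked recovery hazard, slowly
increasing absorbing hazards, 25% initially ill, geometric censoring
masses with 20% never censored on the grid) standing in for templates
estimated from real cohort data.  What it does *not* emulate:
continuous event times (everything lives on the grid), covariate
heterogeneity, dependent censoring, and non-Markov dynamics — passing
operating-characteristic checks on this generator therefore validates
the inferential machinery under the model's assumptions, not robustness
to their violation.

## Monte-Carlo studies and the sizes used

`run_size_study` replays the proportional-hazards test over simulated
two-group datasets and reports rejection fractions; both distances can
share one set of bootstrap draws per study.  The reference points at
n = 125 per group are reproduced at full replication (1000 studies ×
1000 draws, about 5 s per scenario); the n = 1000 row is run at 400 ×
400, a deliberate study-size choice trading Monte-Carlo resolution
(binomial SE ≈ 0.011) for speed.  `run_coverage_study` reports the
fraction of studies in which a band covers the true cumulative hazard
over the *whole* interval — between jump times the step-shaped band is
compared against the supremum of the (increasing) truth on the segment,
so the check is exact, not grid-approximate — and flags configurations
whose mean event count falls below 20, where band construction is
unreliable.  Its diagnostic mode also reports how often *pointwise*
95% intervals cover simultaneously (about 72% in the unit-hazard model
at n = 200 — the quantitative argument for genuine bands).
`run_equality_size_study` does the same for the two KS equality tests
(1000 studies × 500 draws at n = 200 by default).  Per-study seeds are
derived from the root seed and the study index, so studies are
independent and individually reproducible.

## Known limitations

* No smoothed hazard estimation, no Aalen–Johansen transition
  probabilities, and no transformations beyond log and identity.
* The equivalence test's one-sided bands reuse symmetric critical
  values (see above).
* Multistate simulation is O(n · grid) per study and in pure Python per
  subject; it is meant for desk-scale studies, not for n ≫ 10⁵.
* Exact p-value/decision duality requires tie-free bootstrap draws;
  with the discrete Poisson multipliers on tiny samples ties can occur,
  in which case the decision follows the critical-value comparison.
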