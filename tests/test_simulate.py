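import numpy as np
import pytest

from wildna.event_data import TransitionKey, build_counting_data, validate_histories
from wildna.nelson_aalen import nelson_aalen
from wildna.simulate import (
    CompetingRisksScenario,
    ConstantHazardSurvival,
    MultistateTemplate,
    band_covers,
    censoring_time_for_fraction,
    make_synthetic_template,
    run_coverage_study,
    run_size_study,
    scenario,
    simulate_multistate_from_template,
    simulate_two_sample_competing_risks,
)
from wildna.stepfun import StepFunction


class TestCensoringTime:
    def test_closed_form(self):
        assert censoring_time_for_fraction(4.0, 0.25) == pytest.approx(np.log(4) / 4)

    def test_exponential_identity(self):
        assert censoring_time_for_fraction(1.0, np.exp(-1)) == pytest.approx(1.0)

    def test_homogeneity(self):
        c = censoring_time_for_fraction(2.0, 0.3)
        assert censoring_time_for_fraction(4.0, 0.3) == pytest.approx(c / 2)

    @pytest.mark.parametrize("bad", [0.0, 1.0])
    def test_degenerate_fraction_rejected(self, bad):
        with pytest.raises(ValueError):
            censoring_time_for_fraction(1.0, bad)


@pytest.fixture(scope="module")
def big_sample():
    sc = scenario("I", n_per_group=20000, seed=77)
    return sc, simulate_two_sample_competing_risks(sc)


class TestCompetingRisksGenerator:
    def test_cause_fractions_balanced_under_equal_hazards(self, big_sample):
        _, (g1, _) = big_sample
        events = g1[g1["to"] != "cens"]
        assert (events["to"] == "1").mean() == pytest.approx(0.5, abs=0.02)

    def test_censored_fraction_near_target(self, big_sample):
        sc, (g1, g2) = big_sample
        for g in (g1, g2):
            assert (g["to"] == "cens").mean() == pytest.approx(
                sc.censoring_fraction, abs=0.02
            )

    def test_uncensored_event_times_bounded_by_censoring_time(self, big_sample):
        sc, (g1, _) = big_sample
        c = censoring_time_for_fraction(sum(sc.hazards_group1), sc.censoring_fraction)
        assert g1["exit"].max() == pytest.approx(c)

    def test_records_pass_validation(self, big_sample):
        _, (g1, _) = big_sample
        assert validate_histories(g1.head(500), state_space=("0", "1", "2")).ok

    def test_nelson_aalen_slope_recovers_hazard(self, big_sample):
        """Â₀₁(t)/t ≈ α₀₁ = 2 under scenario I at large n."""
        sc, (g1, _) = big_sample
        cd = build_counting_data(g1, TransitionKey("0", "1"), tau=0.3)
        est = nelson_aalen(cd)
        assert est(0.3) / 0.3 == pytest.approx(2.0, rel=0.05)

    def test_invalid_scenario_parameters(self):
        with pytest.raises(ValueError):
            CompetingRisksScenario((0.0, 1.0), (1.0, 1.0))
        with pytest.raises(ValueError):
            scenario("V")


class TestSyntheticTemplate:
    def test_censoring_masses_sum_to_one(self):
        tpl = make_synthetic_template(seed=0)
        assert tpl.censoring.sum() == pytest.approx(1.0)

    def test_absorbing_state_has_no_outgoing_increments(self):
        tpl = make_synthetic_template(seed=0)
        assert all(l != "2" for (l, _) in tpl.increments)

    def test_same_seed_identical_template(self):
        a = make_synthetic_template(seed=5)
        b = make_synthetic_template(seed=5)
        for key in a.increments:
            np.testing.assert_array_equal(a.increments[key], b.increments[key])

    def test_true_cumhaz_is_increment_cumsum(self):
        tpl = make_synthetic_template(seed=0)
        key = TransitionKey("0", "2")
        truth = tpl.true_cumhaz(key)
        assert truth(tpl.tau) == pytest.approx(sum(tpl.increments[("0", "2")]))

    def test_excessive_hazard_rejected(self):
        tpl = make_synthetic_template(seed=0)
        bad = dict(tpl.increments)
        bad[("0", "1")] = np.full(tpl.grid.size, 0.99)
        with pytest.raises(ValueError, match="total discrete hazard"):
            MultistateTemplate(
                tpl.states, tpl.absorbing, tpl.grid, bad, tpl.censoring,
                tpl.initial_distribution,
            )


class TestTemplateSimulation:
    def test_certain_single_transition(self):
        grid = np.array([1.0])
        tpl = MultistateTemplate(
            states=("0", "2"), absorbing=("2",), grid=grid,
            increments={("0", "2"): np.array([1.0])},
            censoring=np.array([0.0, 1.0]),  # never censored on the grid
            initial_distribution={"0": 1.0},
        )
        frame = simulate_multistate_from_template(tpl, 50, seed=1)
        assert len(frame) == 50
        assert (frame["to"] == "2").all()
        assert (frame["exit"] == 1.0).all()

    def test_no_exit_from_absorbing_state(self):
        tpl = make_synthetic_template(seed=2)
        frame = simulate_multistate_from_template(tpl, 300, seed=3)
        assert (frame["from"] != "2").all()

    def test_histories_are_valid(self):
        tpl = make_synthetic_template(seed=2)
        frame = simulate_multistate_from_template(tpl, 300, seed=3)
        assert validate_histories(frame, state_space=("0", "1", "2")).ok

    def test_initial_state_frequencies_match_distribution(self):
        tpl = make_synthetic_template(seed=2)
        frame = simulate_multistate_from_template(tpl, 10000, seed=4)
        first = frame.sort_values("entry").groupby("id").first()
        freq = (first["from"] == "0").mean()
        assert freq == pytest.approx(0.75, abs=0.02)

    def test_estimates_recover_template_hazards(self):
        tpl = make_synthetic_template(seed=2)
        frame = simulate_multistate_from_template(tpl, 6000, seed=5)
        key = TransitionKey("1", "2")
        cd = build_counting_data(frame, key, tau=tpl.tau)
        est = nelson_aalen(cd)
        truth = tpl.true_cumhaz(key)
        mid = tpl.tau / 2
        assert est(mid) == pytest.approx(truth(mid), rel=0.15)

    def test_reproducible_under_seed(self):
        tpl = make_synthetic_template(seed=2)
        a = simulate_multistate_from_template(tpl, 100, seed=9)
        b = simulate_multistate_from_template(tpl, 100, seed=9)
        assert a.equals(b)


class TestBandCovers:
    def test_detects_violation_between_jumps(self):
        lower = StepFunction(np.array([1.0]), np.array([0.0]))
        upper = StepFunction(np.array([1.0]), np.array([1.5]))
        # truth t -> t exceeds 1.5 before t2 = 2
        assert not band_covers(lower, upper, lambda t: np.asarray(t), 1.0, 2.0)
        assert band_covers(lower, upper, lambda t: np.asarray(t), 1.0, 1.4)

    def test_step_truth_checked_on_union_grid(self):
        lower = StepFunction(np.array([1.0]), np.array([0.2]))
        upper = StepFunction(np.array([1.0]), np.array([1.0]))
        truth = StepFunction(np.array([1.5]), np.array([2.0]))
        assert not band_covers(lower, upper, truth, 1.0, 2.0, truth_times=truth.times)


class TestStudies:
    def test_size_study_deterministic_and_bounded(self):
        sc = scenario("I", n_per_group=60, seed=1)
        tab1 = run_size_study(sc, n_studies=8, B=40, rho=("KS", "CvM"), seed=1)
        tab2 = run_size_study(sc, n_studies=8, B=40, rho=("KS", "CvM"), seed=1)
        assert tab1.equals(tab2)
        assert ((tab1["rejection_rate"] >= 0) & (tab1["rejection_rate"] <= 1)).all()

    def test_size_study_monotone_in_alpha(self):
        sc = scenario("IV", n_per_group=60, seed=2)
        lo = run_size_study(sc, n_studies=15, B=60, alpha=0.05, rho="KS", seed=2)
        hi = run_size_study(sc, n_studies=15, B=60, alpha=0.5, rho="KS", seed=2)
        assert (
            hi["rejection_rate"].iloc[0] >= lo["rejection_rate"].iloc[0]
        )

    def test_coverage_study_smoke(self):
        tab = run_coverage_study(
            ConstantHazardSurvival(hazard=1.0, n=100, tau=1.0),
            band_types=("HW_w", "dir_w"), n_studies=10, B=100,
            interval=(0.2, 1.0), seed=3,
        )
        assert set(tab["band_type"]) == {"HW_w", "dir_w"}
        assert ((tab["coverage"] >= 0) & (tab["coverage"] <= 1)).all()

    def test_coverage_one_with_infinite_band(self):
        """A direct band with an infinite critical value always covers."""
        from wildna.bands import BandSpec, build_band
        from wildna.nelson_aalen import fit_nelson_aalen
        from wildna.simulate import _counting_from_exits

        rng = np.random.default_rng(0)
        n = 50
        t = rng.exponential(1.0, n)
        cd = _counting_from_exits(t, np.ones(n, dtype=int), 1, 1.0, n,
                                  TransitionKey("0", "1"))
        fit = fit_nelson_aalen(cd)
        band = build_band(fit, 1e12, BandSpec("dir_w", 0.05, (0.2, 1.0)))
        assert band_covers(band.lower, band.upper, lambda s: np.asarray(s), 0.2, 1.0)
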