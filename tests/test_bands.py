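import numpy as np
import pytest
from scipy.stats import kstwobign

from wildna.bands import (
    BandSpec,
    ConfidenceBandEstimator,
    bb_critical_value,
    build_band,
    difference_band,
    phi_hat,
    sidak_region,
    simultaneous_intervals,
    wb_critical_value,
)
from wildna.event_data import TransitionKey, build_counting_data
from wildna.nelson_aalen import fit_nelson_aalen
from wildna.simulate import _counting_from_exits
from wildna.stepfun import StepFunction
from wildna.wild_bootstrap import (
    MultiplierSpec,
    WildBootstrapDraws,
    empirical_variance,
    wild_bootstrap_paths,
)


class TestPhiHat:
    @pytest.mark.parametrize(
        "sig2,expected", [(0.0, 0.0), (1.0, 0.5), (13 / 12, 13 / 25)]
    )
    def test_values(self, sig2, expected):
        f = phi_hat(StepFunction(np.array([1.0]), np.array([sig2])))
        assert f(1.0) == pytest.approx(expected)

    def test_rejects_negative_variance(self):
        with pytest.raises(ValueError):
            phi_hat(StepFunction(np.array([1.0]), np.array([-0.1])))


class TestBrownianBridgeCriticalValues:
    """Monte-Carlo quantiles against closed-form oracles (modest path
    counts here; the full-accuracy checks run in the acceptance suite)."""

    def test_kolmogorov_point(self):
        target = kstwobign.ppf(0.95)  # 1.3581
        v = bb_critical_value("g2", 0.0, 0.999999, 0.05, n_paths=30000, grid=800,
                              seed=1)
        assert v == pytest.approx(target, abs=0.02)

    def test_degenerate_hall_wellner_point(self):
        # |B0(0.5)| ~ |N(0, 0.25)|: 95% point 1.96 * 0.5
        v = bb_critical_value("g2", 0.5, 0.5, 0.05, n_paths=50000, grid=10, seed=2)
        assert v == pytest.approx(0.98, abs=0.02)

    @pytest.mark.parametrize("phi", [0.2, 0.5, 0.8])
    def test_degenerate_equal_precision_point(self, phi):
        # the weight cancels the standard deviation: quantile of |N(0,1)|
        v = bb_critical_value("g1", phi, phi, 0.05, n_paths=50000, grid=10, seed=3)
        assert v == pytest.approx(1.96, abs=0.03)

    def test_g1_needs_interior_interval(self):
        with pytest.raises(ValueError):
            bb_critical_value("g1", 0.0, 0.5, 0.05)

    def test_deterministic_under_seed(self):
        a = bb_critical_value("g2", 0.1, 0.6, 0.05, n_paths=500, grid=100, seed=9)
        b = bb_critical_value("g2", 0.1, 0.6, 0.05, n_paths=500, grid=100, seed=9)
        assert a == b


def _single_draw(times, path, star, n=1):
    paths = np.asarray([path], dtype=float)
    return WildBootstrapDraws(
        TransitionKey("0", "1"), np.asarray(times, dtype=float), paths,
        np.asarray([star], dtype=float), n=n, B=1, multiplier=MultiplierSpec(),
    )


class TestWildBootstrapCriticalValues:
    def test_single_draw_hall_wellner_transform(self):
        draws = _single_draw([1.0], [1.0], [1.0])
        var = StepFunction(np.array([1.0]), np.array([1.0]))
        assert wb_critical_value(draws, "g2", var, 0.05, (1.0, 1.0)) == pytest.approx(0.5)

    def test_direct_band_quantile_rule(self):
        paths = np.array([[0.1], [0.2], [0.3], [0.4]])
        draws = WildBootstrapDraws(
            TransitionKey("0", "1"), np.array([1.0]), paths, np.zeros_like(paths),
            n=1, B=4, multiplier=MultiplierSpec(),
        )
        assert wb_critical_value(draws, "identity", None, 0.25, (0.0, 2.0)) == 0.3

    def test_all_zero_draws(self):
        draws = _single_draw([1.0], [0.0], [0.0])
        assert wb_critical_value(draws, "identity", None, 0.05, (0.0, 2.0)) == 0.0

    def test_g1_rejects_zero_variance(self):
        draws = _single_draw([1.0], [1.0], [0.0])
        var = StepFunction(np.array([1.0]), np.array([0.0]))
        with pytest.raises(ValueError, match="variance is zero|edges"):
            wb_critical_value(draws, "g1", var, 0.05, (0.5, 1.5))


class TestBuildBand:
    def test_toy_equal_precision_endpoints(self, toy_fit):
        spec = BandSpec("EP_a", 0.05, (1.0, 2.5), variance_source="aalen")
        band = build_band(toy_fit, 2.0, spec)
        assert band.lower(2.0) == pytest.approx(0.1970, abs=5e-4)
        assert band.upper(2.0) == pytest.approx(3.5253, abs=5e-4)

    def test_zero_critical_value_collapses_to_estimate(self, toy_fit):
        for bt in ("EP_a", "HW_a", "dir_w"):
            spec = BandSpec(bt, 0.05, (1.0, 2.5), variance_source="aalen")
            band = build_band(toy_fit, 0.0, spec)
            np.testing.assert_allclose(band.lower.values, band.upper.values)
            assert band.lower(2.0) == pytest.approx(5 / 6)

    def test_toy_direct_band(self, toy_fit):
        spec = BandSpec("dir_w", 0.05, (1.0, 2.5))
        band = build_band(toy_fit, 0.5, spec)
        assert band.upper(2.0) - band.lower(2.0) == pytest.approx(2 * 0.5 / np.sqrt(3))

    def test_transformed_band_needs_positive_estimate_at_t1(self, toy_fit):
        spec = BandSpec("EP_a", 0.05, (0.5, 2.5), variance_source="aalen")
        with pytest.raises(ValueError, match="move t1"):
            build_band(toy_fit, 2.0, spec)

    def test_bands_contain_estimate(self, toy_fit):
        for bt in ("EP_a", "HW_a", "dir_w"):
            spec = BandSpec(bt, 0.05, (1.0, 2.5), variance_source="greenwood")
            band = build_band(toy_fit, 1.3, spec)
            t = band.lower.times
            est = toy_fit.estimate(t)
            assert np.all(band.lower(t) <= est) and np.all(est <= band.upper(t))


class TestDifferenceBand:
    @pytest.fixture
    def fits_draws(self, toy_frame):
        cd1 = build_counting_data(toy_frame, TransitionKey("0", "2"), tau=3.0)
        cd2 = build_counting_data(toy_frame, TransitionKey("0", "1"), tau=3.0)
        f1, f2 = fit_nelson_aalen(cd1), fit_nelson_aalen(cd2)
        d1 = wild_bootstrap_paths(cd1, MultiplierSpec("normal", 1), 300)
        d2 = wild_bootstrap_paths(cd2, MultiplierSpec("normal", 2), 300)
        return f1, f2, d1, d2

    def test_identical_draws_give_zero_width(self, fits_draws):
        f1, _, d1, _ = fits_draws
        band = difference_band(f1, f1, d1, d1, 0.05, (0.0, 3.0))
        assert band.critical_value == 0.0
        np.testing.assert_allclose(band.lower.values, band.upper.values)

    def test_reduces_to_direct_critical_value_against_empty(self, fits_draws):
        f1, f2, d1, d2 = fits_draws
        band = difference_band(f1, f2, d1, d2, 0.05, (0.0, 3.0))
        direct = wb_critical_value(d1, "identity", None, 0.05, (0.0, 3.0))
        assert band.critical_value == pytest.approx(direct)

    def test_mismatched_n_rejected(self, fits_draws):
        from dataclasses import replace

        f1, f2, d1, d2 = fits_draws
        with pytest.raises(ValueError, match="shared sample size"):
            difference_band(f1, replace(f2, n=99), d1, d2, 0.05, (0.0, 3.0))


class TestSimultaneousIntervals:
    @pytest.fixture
    def fit_draws(self, toy_fit, toy_cd):
        return toy_fit, wild_bootstrap_paths(toy_cd, MultiplierSpec("normal", 4), 400)

    def test_single_timepoint_is_pointwise_interval(self, fit_draws):
        fit, draws = fit_draws
        iv = simultaneous_intervals(fit, draws, [2.0], 0.05)
        assert len(iv) == 1
        assert iv["lower"][0] < fit.estimate(2.0) < iv["upper"][0]

    def test_critical_value_monotone_in_set(self, fit_draws):
        fit, draws = fit_draws
        c1 = simultaneous_intervals(fit, draws, [2.0], 0.05).attrs["critical_value"]
        c2 = simultaneous_intervals(fit, draws, [1.0, 2.0], 0.05).attrs["critical_value"]
        assert c2 >= c1

    def test_empty_set_rejected(self, fit_draws):
        fit, draws = fit_draws
        with pytest.raises(ValueError):
            simultaneous_intervals(fit, draws, [], 0.05)


class TestSidakRegion:
    def test_single_component_is_plain_interval(self, toy_fit, toy_cd):
        draws = wild_bootstrap_paths(toy_cd, MultiplierSpec("normal", 4), 400)
        reg = sidak_region([toy_fit], [draws], 2.0, 0.05)
        iv = simultaneous_intervals(toy_fit, draws, [2.0], 0.05)
        assert reg["lower"][0] == pytest.approx(iv["lower"][0])
        assert reg.attrs["component_level"] == pytest.approx(0.95)

    def test_two_components_use_sidak_level(self, toy_fit, toy_cd):
        draws = wild_bootstrap_paths(toy_cd, MultiplierSpec("normal", 4), 400)
        reg = sidak_region([toy_fit] * 2, [draws] * 2, 2.0, 0.05)
        assert reg.attrs["component_level"] == pytest.approx(0.95**0.5)

    def test_component_level_increases_with_k(self, toy_fit, toy_cd):
        draws = wild_bootstrap_paths(toy_cd, MultiplierSpec("normal", 4), 400)
        levels = [
            sidak_region([toy_fit] * k, [draws] * k, 2.0, 0.05).attrs["component_level"]
            for k in (1, 2, 4)
        ]
        assert levels == sorted(levels)


class TestEstimatorSurface:
    def test_band_estimator_deterministic(self, toy_frame):
        kw = dict(transition=("0", "2"), band_type="dir_w", interval=(0.5, 2.5),
                  B=200, random_state=3, tau=3.0)
        a = ConfidenceBandEstimator(**kw).fit(toy_frame)
        b = ConfidenceBandEstimator(**kw).fit(toy_frame)
        assert a.critical_value_ == b.critical_value_
        np.testing.assert_array_equal(a.predict([1.0, 2.0]), b.predict([1.0, 2.0]))

    @pytest.mark.parametrize("band_type", ["EP_a", "HW_a", "EP_w", "HW_w", "dir_w"])
    def test_all_band_types_fit(self, band_type, toy_frame):
        est = ConfidenceBandEstimator(
            transition=("0", "2"), band_type=band_type, interval=(1.0, 2.5),
            B=100, bb_paths=200, random_state=1, tau=3.0,
        ).fit(toy_frame)
        assert est.critical_value_ > 0
        lo, hi = est.predict([2.0])[0]
        assert lo < 5 / 6 < hi


def test_bb_and_wb_calibrations_agree_for_large_n():
    """Both calibrations of the Hall–Wellner band give similar widths in
    a moderately large constant-hazard sample (median ratio within 10%)."""
    rng = np.random.default_rng(8)
    n = 1000
    t = rng.exponential(1.0, n)
    cd = _counting_from_exits(t, np.ones(n, dtype=int), 1, 1.0, n,
                              TransitionKey("0", "1"))
    fit = fit_nelson_aalen(cd)
    interval = (0.2, 1.0)
    draws = wild_bootstrap_paths(cd, MultiplierSpec("normal", 11), 2000)
    var_emp = empirical_variance(draws)
    c_wb = wb_critical_value(draws, "g2", var_emp, 0.05, interval)
    band_wb = build_band(fit, c_wb, BandSpec("HW_w", 0.05, interval), variance=var_emp)
    phi = phi_hat(fit.var_greenwood)
    c_bb = bb_critical_value("g2", float(phi(0.2)), float(phi(1.0)), 0.05,
                             n_paths=4000, grid=500, seed=12)
    band_bb = build_band(fit, c_bb, BandSpec("HW_a", 0.05, interval))
    t_eval = band_wb.lower.times
    width_wb = band_wb.upper(t_eval) - band_wb.lower(t_eval)
    width_bb = band_bb.upper(t_eval) - band_bb.lower(t_eval)
    ratio = np.median(width_wb / width_bb)
    assert 0.9 <= ratio <= 1.1
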