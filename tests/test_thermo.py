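"""Two-state adsorption model: free energies, threshold and equivalent angles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import monowet as mw
from monowet.thermo import DEFAULT_MODEL, GAMMA_WATER, round_half_away


def brute_force_root(f, lo=0.0, hi=180.0, n=1_800_000):
    """Independent oracle: sign-change scan on a dense uniform grid."""
    t = np.linspace(lo, hi, n)
    ft = f(t)
    idx = np.nonzero(np.diff(np.sign(ft)) != 0)[0]
    assert idx.size >= 1
    i = idx[0]
    # linear interpolation inside the bracketing cell
    return t[i] - ft[i] * (t[i + 1] - t[i]) / (ft[i + 1] - ft[i])


class TestAdhesionModel:
    @pytest.mark.parametrize(
        "theta, expected",
        [(0.0, 57.0), (113.0, 52.0), (180.0, 57.0 - 5.0 / 113.0 * 180.0)],
    )
    def test_linear_law_through_anchors(self, theta, expected):
        assert mw.wsl_at(DEFAULT_MODEL, theta) == pytest.approx(expected, abs=1e-12)

    def test_constant_model(self):
        model = mw.AdhesionModel(wll=49, wsl_intercept=54, wsl_slope=0.0)
        assert mw.wsl_at(model, 90.0) == 54.0

    def test_from_points_matches_default(self):
        model = mw.AdhesionModel.from_wsl_points((0, 57), (113, 52), wll=49)
        assert model == DEFAULT_MODEL

    @pytest.mark.parametrize("theta", [-1.0, 180.5])
    def test_out_of_range_angle_rejected(self, theta):
        with pytest.raises(mw.DomainError):
            mw.wsl_at(DEFAULT_MODEL, theta)

    def test_invalid_models_rejected(self):
        with pytest.raises(mw.DomainError):
            mw.AdhesionModel(wll=-1)
        with pytest.raises(mw.DomainError):
            mw.AdhesionModel(wsl_intercept=10, wsl_slope=-1.0)  # negative wsl(180)


class TestFreeEnergy:
    @pytest.mark.parametrize(
        "theta, expected",
        [(0.0, 39.5), (113.0, -55.63264125122771)],
    )
    def test_breakdown_totals(self, theta, expected):
        bd = mw.adsorption_free_energy(theta, DEFAULT_MODEL, 72.0)
        assert bd.total == pytest.approx(expected, abs=1e-9)

    @given(theta=st.floats(0, 180), gamma=st.floats(1, 200))
    @settings(max_examples=50, deadline=None)
    def test_breakdown_is_additive(self, theta, gamma):
        bd = mw.adsorption_free_energy(theta, DEFAULT_MODEL, gamma)
        assert bd.total == pytest.approx(
            bd.term_ll + bd.term_sl + bd.term_adhesion, abs=1e-9
        )

    def test_nonpositive_gamma_rejected(self):
        with pytest.raises(mw.DomainError):
            mw.adsorption_free_energy(45.0, DEFAULT_MODEL, 0.0)

    def test_zero_at_threshold_angle(self):
        theta_ads = mw.solve_adsorption_angle()
        assert mw.adsorption_free_energy(theta_ads).total == pytest.approx(
            0.0, abs=1e-9
        )

    def test_strictly_decreasing_with_unique_root(self):
        # gamma*sin(theta) dominates the tiny wsl slope on [5, 175] deg, so
        # dF is strictly decreasing there and the root is unique
        grid = np.arange(0.0, 180.0 + 1e-9, 0.1)
        vals = np.array(
            [mw.adsorption_free_energy(t).total for t in grid]
        )
        inner = (grid >= 5.0) & (grid <= 175.0)
        assert np.all(np.diff(vals[inner]) < 0)
        assert np.count_nonzero(np.diff(np.sign(vals)) != 0) == 1


class TestThresholdSolver:
    def test_matches_brute_force_scan(self):
        def f(t):
            return 49 / 2 - (57 - 5 / 113 * t) + 72 * np.cos(np.radians(t))

        oracle = brute_force_root(f)
        assert mw.solve_adsorption_angle() == pytest.approx(oracle, abs=1e-4)
        assert mw.solve_adsorption_angle() == pytest.approx(65.7328, abs=1e-3)

    def test_headline_value_rounds_to_66(self):
        assert round_half_away(mw.solve_adsorption_angle()) == 66

    def test_fixed_point_form_consistent(self):
        # the root of dF = 0 also satisfies cos(t) = (2 wsl(t) - wll)/(2 gamma)
        t = mw.solve_adsorption_angle()
        lhs = math.cos(math.radians(t))
        rhs = (2 * DEFAULT_MODEL.wsl(t) - DEFAULT_MODEL.wll) / (2 * GAMMA_WATER)
        assert math.degrees(abs(math.acos(lhs) - math.acos(rhs))) < 1e-6

    def test_constant_wsl_half_wll_gives_90(self):
        model = mw.AdhesionModel(wll=50, wsl_intercept=25, wsl_slope=0.0)
        assert mw.solve_adsorption_angle(model, 72.0) == pytest.approx(90.0, abs=1e-7)

    def test_never_adsorbs_is_typed(self):
        model = mw.AdhesionModel(wll=500, wsl_intercept=57, wsl_slope=0.0)
        with pytest.raises(mw.NeverAdsorbsError):
            mw.solve_adsorption_angle(model, 72.0)

    def test_always_adsorbs_is_typed(self):
        model = mw.AdhesionModel(wll=10, wsl_intercept=200, wsl_slope=0.0)
        with pytest.raises(mw.AlwaysAdsorbsError):
            mw.solve_adsorption_angle(model, 72.0)

    def test_hydrocarbon_limit_agrees_with_full_solver(self):
        # wll = 2*gamma_hc and constant wsl = 2*gamma_hc reduce the full
        # model to the hydrocarbon-ratio formula
        gamma_hc = 25.0
        model = mw.AdhesionModel(
            wll=2 * gamma_hc, wsl_intercept=2 * gamma_hc, wsl_slope=0.0
        )
        assert mw.solve_adsorption_angle(model, 72.0) == pytest.approx(
            mw.theta_ads_hydrocarbon(gamma_hc, 72.0), abs=1e-6
        )


class TestHydrocarbonEstimate:
    @pytest.mark.parametrize(
        "gamma_hc, expected",
        [(28.0, 67.11461952384143), (23.0, 71.37066942530411), (72.0, 0.0)],
    )
    def test_alkane_ratio_angles(self, gamma_hc, expected):
        assert mw.theta_ads_hydrocarbon(gamma_hc, 72.0) == pytest.approx(
            expected, abs=1e-9
        )

    def test_ratio_above_one_rejected(self):
        with pytest.raises(mw.DomainError):
            mw.theta_ads_hydrocarbon(80.0, 72.0)

    def test_nonzero_hydrocarbon_angle(self):
        got = mw.theta_ads_hydrocarbon(28.0, 72.0, theta_hc=30.0)
        assert got == pytest.approx(
            math.degrees(math.acos(28 * math.cos(math.radians(30)) / 72)), abs=1e-12
        )


class TestLinearizedFreeEnergy:
    @pytest.mark.parametrize(
        "theta, theta_ads, gamma, expected",
        [
            (65.7, 65.7, 72.0, 0.0),
            (0.0, 65.7, 72.0, 42.37096618043218),
            (180.0, 90.0, 72.0, -72.0),
        ],
    )
    def test_values(self, theta, theta_ads, gamma, expected):
        assert mw.linearized_free_energy(theta, theta_ads, gamma) == pytest.approx(
            expected, abs=1e-9
        )

    def test_linearization_error_bound(self):
        # |linearized - exact| = |wsl(theta_ads) - wsl(theta)|
        #                     <= |slope| * |theta - theta_ads|
        theta_ads = mw.solve_adsorption_angle()
        slope = abs(DEFAULT_MODEL.wsl_slope)
        for theta in np.linspace(0, 180, 181):
            exact = mw.adsorption_free_energy(theta).total
            approx = mw.linearized_free_energy(theta, theta_ads)
            assert abs(approx - exact) <= slope * abs(theta - theta_ads) + 1e-9


class TestAirWaterInterface:
    @pytest.mark.parametrize(
        "wll, gamma, expected",
        [(49.0, 72.0, -47.5), (144.0, 72.0, 0.0), (49.0, 22.0, 2.5)],
    )
    def test_free_energy(self, wll, gamma, expected):
        model = mw.AdhesionModel(wll=wll)
        assert mw.air_water_free_energy(model, gamma) == pytest.approx(
            expected, abs=1e-12
        )

    def test_equivalent_angle_default_model(self):
        got = mw.equivalent_contact_angle()
        assert got == pytest.approx(105.8663151741, abs=1e-4)
        # consistency: a solid at theta* has the air-water free energy
        bd = mw.adsorption_free_energy(got)
        assert bd.total == pytest.approx(mw.air_water_free_energy(), abs=1e-6)

    def test_equivalent_angle_complete_wetting_limit(self):
        # wsl = 2*gamma makes cos(theta*) = 1, i.e. theta* = 0
        model = mw.AdhesionModel(wll=49, wsl_intercept=144.0, wsl_slope=0.0)
        assert mw.equivalent_contact_angle(model, 72.0) == pytest.approx(
            0.0, abs=1e-5
        )

    def test_no_equivalent_angle_is_typed(self):
        model = mw.AdhesionModel(wll=49, wsl_intercept=400.0, wsl_slope=0.0)
        with pytest.raises(mw.NoEquivalentAngleError):
            mw.equivalent_contact_angle(model, 72.0)


class TestNeatOrganicLimit:
    def test_default_evaluation_at_in_water_threshold(self):
        got = mw.neat_organic_free_energy(gamma_alc=22.0)
        assert got == pytest.approx(-7.5914692677, abs=1e-6)
        assert round_half_away(got) == -8

    def test_explicit_evaluation_angle(self):
        assert mw.neat_organic_free_energy(
            gamma_alc=22.0, theta_eval=0.0
        ) == pytest.approx(24.5 - 57.0 + 22.0, abs=1e-12)

    def test_cancellation_leaves_gamma_alc(self):
        model = mw.AdhesionModel(wll=100.0, wsl_intercept=50.0, wsl_slope=0.0)
        assert mw.neat_organic_free_energy(
            model, gamma_alc=31.0, theta_eval=40.0
        ) == pytest.approx(31.0, abs=1e-12)
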