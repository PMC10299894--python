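"""Solvent-exchange model: adhesion-tension lines and composition profiles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import monowet as mw
from monowet.mixtures import fit_mixture_tension, zisman_from_endpoints
from monowet.synth import make_mixture_table


def cosd(t):
    return math.cos(math.radians(t))


class TestZismanLine:
    @given(theta_w=st.floats(0, 180))
    @settings(max_examples=50, deadline=None)
    def test_endpoint_exactness(self, theta_w):
        # at gamma_w the line reproduces the water adhesion tension; at
        # gamma_alc it reproduces gamma_alc itself, for any theta_w
        line = zisman_from_endpoints(72.0, theta_w, 22.0)
        assert line.adhesion_tension(72.0) == pytest.approx(
            72.0 * cosd(theta_w), abs=1e-9
        )
        assert line.adhesion_tension(22.0) == pytest.approx(22.0, abs=1e-9)

    def test_hand_computed_coefficients(self):
        line = zisman_from_endpoints(72.0, 104.0, 22.0)
        assert line.c1 == pytest.approx(-0.7883675296635215, abs=1e-9)
        assert line.c0 == pytest.approx(39.34408565259747, abs=1e-9)

    def test_midrange_evaluation(self):
        line = zisman_from_endpoints(72.0, 45.0, 22.0)
        assert mw.zisman_adhesion_tension(47.0, line) == pytest.approx(
            36.45584412271571, abs=1e-9
        )

    def test_degenerate_line_at_critical_angle(self):
        theta_wc = mw.critical_water_angle(72.0, 22.0)
        line = zisman_from_endpoints(72.0, theta_wc, 22.0)
        assert line.c1 == pytest.approx(0.0, abs=1e-12)
        assert line.c0 == pytest.approx(22.0, abs=1e-9)

    def test_complete_wetting_limit(self):
        line = zisman_from_endpoints(44.0, 0.0, 22.0)
        assert line.c1 == pytest.approx(1.0, abs=1e-12)
        assert line.c0 == pytest.approx(0.0, abs=1e-12)

    def test_equal_endpoints_rejected(self):
        with pytest.raises(mw.DomainError):
            zisman_from_endpoints(30.0, 45.0, 30.0)

    @pytest.mark.parametrize(
        "theta_w, sign", [(45.0, 1), (66.0, 1), (104.0, -1)]
    )
    def test_slope_sign_law(self, theta_w, sign):
        # d(gamma cos theta)/d gamma > 0 iff theta_w < theta_wc (~72.2 deg)
        line = zisman_from_endpoints(72.0, theta_w, 22.0)
        assert np.sign(line.c1) == sign


class TestCriticalAngle:
    @pytest.mark.parametrize(
        "gw, galc, expected",
        [(72.0, 22.0, 72.20840942699236), (72.0, 36.0, 60.0), (50.0, 50.0, 0.0)],
    )
    def test_values(self, gw, galc, expected):
        assert mw.critical_water_angle(gw, galc) == pytest.approx(expected, abs=1e-9)

    def test_invalid_ratio_rejected(self):
        with pytest.raises(mw.DomainError):
            mw.critical_water_angle(22.0, 72.0)


class TestMixtureFit:
    def test_linear_two_point_midpoint(self):
        curve = fit_mixture_tension([0.0, 1.0], [72.0, 22.0], kind="linear")
        assert curve(0.5) == pytest.approx(47.0, abs=1e-12)

    def test_interpolation_identity(self):
        x = np.array([0.0, 0.05, 0.1, 0.3, 0.6, 1.0])
        gamma = np.array([72.0, 58.0, 50.0, 38.0, 28.0, 22.0])
        curve = fit_mixture_tension(x, gamma)
        assert np.allclose(curve(x), gamma, atol=1e-12)

    def test_pchip_has_no_overshoot(self):
        x = np.array([0.0, 0.05, 0.1, 0.3, 0.6, 1.0])
        gamma = np.array([72.0, 58.0, 50.0, 38.0, 28.0, 22.0])
        curve = fit_mixture_tension(x, gamma)
        fine = curve(np.linspace(0, 1, 2001))
        assert np.all(np.diff(fine) <= 1e-12)
        assert fine.min() >= 22.0 - 1e-9 and fine.max() <= 72.0 + 1e-9

    def test_parametric_fit_recovers_noisy_endpoints(self):
        table, _ = make_mixture_table(
            shape="exponential", n_points=25, noise_sd=0.5, seed=11
        )
        curve = fit_mixture_tension(
            table["x"], table["gamma_mN_per_m"], kind="exponential"
        )
        assert curve.gamma_w == pytest.approx(72.0, abs=1.0)
        assert curve.gamma_alc == pytest.approx(22.0, abs=1.0)

    def test_non_monotone_data_warns_and_smooths(self):
        with pytest.warns(UserWarning, match="isotonic"):
            curve = fit_mixture_tension(
                [0.0, 0.2, 0.5, 1.0], [72.0, 75.0, 40.0, 22.0]
            )
        fine = curve(np.linspace(0, 1, 501))
        assert np.all(np.diff(fine) <= 1e-9)

    def test_too_few_points_rejected(self):
        with pytest.raises(mw.DomainError):
            fit_mixture_tension([0.0, 1.0], [72.0, 22.0])

    def test_exclusion_mask_drops_off_trend_point(self):
        x = [0.0, 0.1, 0.3, 1.0]
        gamma = [72.0, 99.0, 38.0, 22.0]
        curve = fit_mixture_tension(x, gamma, exclude=[False, True, False, False])
        assert curve(0.0) == pytest.approx(72.0, abs=1e-12)


@pytest.fixture(scope="module")
def default_curve():
    table, _ = make_mixture_table(shape="exponential", n_points=25)
    return fit_mixture_tension(table["x"], table["gamma_mN_per_m"])


class TestThetaAdsProfile:
    def test_neat_water_reproduces_66(self, default_curve):
        prof = mw.theta_ads_profile(default_curve, x_grid=[0.0])
        assert mw.round_half_away(prof["theta_ads_deg"][0]) == 66

    def test_monotone_nonincreasing(self, default_curve):
        prof = mw.theta_ads_profile(default_curve, x_grid=np.linspace(0, 0.2, 21))
        theta = prof["theta_ads_deg"].to_numpy()
        assert np.all(np.diff(theta[np.isfinite(theta)]) <= 1e-9)

    def test_solver_agrees_with_threshold_solver(self, default_curve):
        x = 0.1
        gamma_x = float(default_curve(x))
        prof = mw.theta_ads_profile(default_curve, x_grid=[x])
        assert prof["theta_ads_deg"][0] == pytest.approx(
            mw.solve_adsorption_angle(gamma=gamma_x), abs=1e-9
        )

    def test_collapsed_threshold_flagged(self):
        # gamma(x) far below (2 wsl - wll)/2 forces cos > 1: every
        # substrate adsorbs and the row carries the typed marker
        curve = fit_mixture_tension([0.0, 0.5, 1.0], [72.0, 20.0, 10.0])
        prof = mw.theta_ads_profile(curve, x_grid=[1.0])
        assert prof["theta_ads_deg"][0] == 0.0
        assert "always_adsorbs" in prof["flag"][0]
        assert "beyond_solubility_limit" in prof["flag"][0]


class TestFreeEnergyProfile:
    def test_constant_at_critical_angle(self, default_curve):
        theta_wc = mw.critical_water_angle(72.0, 22.0)
        prof = mw.free_energy_profile(
            default_curve, mw.SubstrateState(theta_wc), gamma_alc=22.0,
            x_grid=np.linspace(0, 1, 11),
        )
        dfa = prof["free_energy_mN_per_m"].to_numpy()
        assert np.ptp(dfa) < 1e-9

    @pytest.mark.parametrize("theta_w", [45.0, 66.0, 104.0])
    def test_profiles_converge_in_neat_organic(self, default_curve, theta_w):
        # every substrate reaches wll/2 - wsl + gamma_alc at gamma = gamma_alc
        prof = mw.free_energy_profile(
            default_curve, mw.SubstrateState(theta_w), gamma_alc=22.0, x_grid=[1.0]
        )
        assert prof["free_energy_mN_per_m"][0] == pytest.approx(
            mw.neat_organic_free_energy(gamma_alc=22.0), abs=1e-6
        )

    def test_zero_crossing_tension_for_mildly_hydrophilic_substrate(
        self, default_curve
    ):
        # for theta_w = 45 deg the profile crosses dF = 0 where the mixture
        # tension is about 35 mN/m (inverting the adhesion line)
        prof = mw.free_energy_profile(
            default_curve, mw.SubstrateState(45.0), gamma_alc=22.0,
            x_grid=np.linspace(0, 1, 2001),
        )
        dfa = prof["free_energy_mN_per_m"].to_numpy()
        gam = prof["gamma_mN_per_m"].to_numpy()
        i = int(np.argmin(np.abs(dfa)))
        assert gam[i] == pytest.approx(35.13, abs=0.1)

    def test_solubility_limit_flagged_not_refused(self, default_curve):
        prof = mw.free_energy_profile(
            default_curve, mw.SubstrateState(45.0), x_grid=[0.1, 0.5]
        )
        assert prof["flag"][0] == ""
        assert prof["flag"][1] == "beyond_solubility_limit"
        assert np.isfinite(prof["free_energy_mN_per_m"][1])
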