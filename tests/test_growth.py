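"""Growth models: curvature laws, fitting, BIC, θ(t) dynamics, k_on."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from coatfit import (
    compare_models_bic,
    compute_A0,
    fit_growth_model,
    fit_kon,
    model_predict,
    theta_of_time,
)
from coatfit.growth import THETA_FLOOR, observable_from_curvature

GAMMA, H0 = 9.4e-3, 13.9e-3  # SK-MEL-2 curvature-fit parameters


class TestCurvatureLaws:
    def test_coopcm_tanh_value(self):
        # independent high-precision evaluation of H0*tanh(gamma*pi/H0)
        H = model_predict("CoopCM", (GAMMA, H0), "H", math.pi)
        assert H == pytest.approx(0.0135090, abs=2e-6)

    def test_coopcm_small_angle_slope(self):
        th = 1e-6
        H = model_predict("CoopCM", (GAMMA, H0), "H", th)
        assert H / th == pytest.approx(GAMMA, rel=1e-6)

    def test_coopcm_edge_length_limits(self):
        eps0 = model_predict("CoopCM", (GAMMA, H0), "epsilon", 1e-8)
        assert eps0 == pytest.approx(2 * math.pi / GAMMA, rel=1e-6)
        eps_pi = model_predict("CoopCM", (GAMMA, H0), "epsilon", math.pi)
        assert abs(eps_pi) < 1e-10

    def test_coopcm_edge_length_monotone_decreasing(self):
        th = np.linspace(1e-4, math.pi, 2000)
        eps = model_predict("CoopCM", (GAMMA, H0), "epsilon", th)
        assert np.all(np.diff(eps) < 0)

    def test_cam_constant_area_ccm_constant_curvature(self):
        th = np.linspace(0.1, math.pi, 50)
        A = model_predict("CAM", 54_000.0, "A", th)
        assert np.allclose(A, 54_000.0, rtol=1e-12)
        H = model_predict("CCM", 90.0, "H", th)
        assert np.allclose(H, 1 / 90.0, rtol=1e-12)

    def test_linearcm_solves_linear_ode(self):
        sol = solve_ivp(
            lambda t, h: GAMMA * (1 - h[0] / H0),
            (0, math.pi),
            [0.0],
            rtol=1e-11,
            atol=1e-14,
            dense_output=True,
        )
        th = np.linspace(1e-3, math.pi, 200)
        assert np.allclose(
            sol.sol(th)[0], model_predict("LinearCM", (GAMMA, H0), "H", th), atol=1e-9
        )

    def test_theta_domain_error(self):
        with pytest.raises(ValueError):
            model_predict("CoopCM", (GAMMA, H0), "H", 0.0)


class TestFitting:
    def test_ccm_noiseless_exact_recovery(self):
        th = np.linspace(0.2, 3.0, 40)
        y = observable_from_curvature(np.full_like(th, 1 / 90.0), th, "A")
        f = fit_growth_model(th, y, "CCM", "A")
        assert f.params_["R"] == pytest.approx(90.0, rel=1e-6)
        assert f.converged_

    def test_coopcm_noisy_recovery(self):
        rng = np.random.default_rng(1)
        th = rng.uniform(math.radians(10), math.radians(170), 1500)
        H = H0 * np.tanh(GAMMA * th / H0) + rng.normal(0, 0.0015, th.size)
        f = fit_growth_model(th, H, "CoopCM", "H")
        assert f.params_["gamma"] == pytest.approx(GAMMA, rel=0.05)
        assert f.params_["H0"] == pytest.approx(H0, rel=0.05)
        assert f.R0_ == pytest.approx(1 / f.params_["H0"], rel=1e-12)
        assert 0 < f.A0_ < 1

    def test_zero_theta_substitution(self):
        th = np.array([0.0, 0.0, 0.5, 1.0, 2.0, 2.5])
        H = H0 * np.tanh(GAMMA * np.maximum(th, THETA_FLOOR) / H0)
        f = fit_growth_model(th, H, "CoopCM", "H")
        assert np.isfinite(f.rss_)
        assert f.theta_.min() >= THETA_FLOOR

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            fit_growth_model([0.1, 0.2], [1e-3, 2e-3], "CCM", "H")


class TestA0:
    @pytest.mark.parametrize(
        "gamma, h0, expected",
        [(9.4e-3, 13.9e-3, 0.51), (7.9e-3, 11.8e-3, 0.52), (8.2e-3, 11.3e-3, 0.45)],
    )
    def test_flat_preassembly_fraction(self, gamma, h0, expected):
        assert compute_A0(gamma, h0) == pytest.approx(expected, abs=0.02)

    def test_a0_agrees_across_observables_on_shared_data(self):
        rng = np.random.default_rng(3)
        th = rng.uniform(math.radians(15), math.radians(170), 2000)
        H_true = H0 * np.tanh(GAMMA * th / H0)
        a0 = []
        for obs, rel_noise in (("H", 0.05), ("A", 0.05), ("epsilon", 0.05)):
            y = observable_from_curvature(H_true, th, obs)
            y = y * (1 + rng.normal(0, rel_noise, th.size))
            f = fit_growth_model(th, y, "CoopCM", obs)
            a0.append(f.A0_)
        assert max(a0) - min(a0) < 0.05


class TestBIC:
    def test_penalty_arithmetic(self):
        rng = np.random.default_rng(0)
        th = rng.uniform(0.3, 3.0, 200)
        H = np.full_like(th, 1 / 90.0) + rng.normal(0, 1e-3, th.size)
        ccm = fit_growth_model(th, H, "CCM", "H")  # k = 1
        coop = fit_growth_model(th, H, "CoopCM", "H")  # k = 2
        # with near-identical RSS the 1-parameter model wins by ~ln(n)
        assert ccm.bic_ < coop.bic_
        rss_term = len(th) * (
            math.log(coop.rss_ / len(th)) - math.log(ccm.rss_ / len(th))
        )
        assert (coop.bic_ - ccm.bic_) == pytest.approx(
            math.log(len(th)) + rss_term, abs=1e-9
        )

    def test_generating_model_selected(self):
        rng = np.random.default_rng(5)
        th = rng.uniform(math.radians(10), math.radians(170), 1500)
        H = H0 * np.tanh(GAMMA * th / H0) + rng.normal(0, 0.0015, th.size)
        fits = [fit_growth_model(th, H, m, "H") for m in ("CAM", "CCM", "CoopCM")]
        ranked = compare_models_bic(fits)
        assert ranked[0][0].name == "CoopCM"
        assert ranked[0][1] == 0.0

    def test_mismatched_data_rejected(self):
        rng = np.random.default_rng(6)
        th = rng.uniform(0.3, 3.0, 100)
        H = np.full_like(th, 0.01)
        f1 = fit_growth_model(th, H, "CCM", "H")
        f2 = fit_growth_model(th[:-1], H[:-1], "CoopCM", "H")
        with pytest.raises(ValueError):
            compare_models_bic([f1, f2])


class TestThetaOfTime:
    def test_starts_at_zero_and_clamps(self):
        c = theta_of_time([0.0, 50.0], GAMMA, H0, 78.1, method="closed_form")
        assert c.theta[0] == 0.0
        assert c.theta[1] == pytest.approx(math.pi)

    def test_square_root_scaling(self):
        for method in ("closed_form", "ode"):
            t = np.array([1e-8, 4e-8])
            c = theta_of_time(t, GAMMA, H0, 78.1, method=method)
            assert c.theta[1] / c.theta[0] == pytest.approx(2.0, rel=1e-4)

    def test_ode_matches_closed_form_in_asymptotic_regime(self):
        t = np.geomspace(1e-9, 1e-6, 40)
        ode = theta_of_time(t, GAMMA, H0, 78.1, method="ode").theta
        cf = theta_of_time(t, GAMMA, H0, 78.1, method="closed_form").theta
        assert np.max(np.abs(ode - cf) / ode) <= 1e-6

    def test_ode_monotone_nondecreasing(self):
        t = np.linspace(0.0, 1.2, 300)
        th = theta_of_time(t, GAMMA, H0, 78.1, method="ode").theta
        assert np.all(np.diff(th) >= -1e-12)
        assert th.max() <= math.pi + 1e-12

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            theta_of_time([0.5], -1.0, H0, 78.1)


class TestKon:
    def test_noiseless_recovery(self):
        t = np.linspace(0.01, 0.9, 60)
        th = theta_of_time(t, GAMMA, H0, 78.1).theta
        assert fit_kon(t, th, GAMMA, H0) == pytest.approx(78.1, rel=1e-4)

    def test_noisy_recovery(self):
        errs = []
        for s in range(20):
            rng = np.random.default_rng(s)
            t = rng.uniform(0, 1, 400)
            th = theta_of_time(t, GAMMA, H0, 78.1).theta + np.radians(
                rng.normal(0, 5, 400)
            )
            errs.append(abs(fit_kon(t, th, GAMMA, H0) - 78.1) / 78.1)
        assert np.median(errs) < 0.05

    def test_doubling_kon_halves_time_to_fixed_theta(self):
        th_target = 1.5
        c1 = _time_to_theta(th_target, 78.1)
        c2 = _time_to_theta(th_target, 156.2)
        assert c1 / c2 == pytest.approx(2.0, rel=1e-6)

    def test_degenerate_time_axis(self):
        with pytest.raises(ValueError):
            fit_kon([0.5, 0.5], [1.0, 1.1], GAMMA, H0)


def _time_to_theta(theta_target, kon):
    # invert the closed form: t = theta^2 / C(kon)
    coeff = 24 * GAMMA * kon / (8 * GAMMA**2 / H0**2 - 1)
    return theta_target**2 / coeff


class TestLinkageSensitivity:
    def _synthetic_sites(self, n=800, seed=2):
        rng = np.random.default_rng(seed)
        th = rng.uniform(math.radians(15), math.radians(170), n)
        H = H0 * np.tanh(GAMMA * th / H0) * (1 + rng.normal(0, 0.05, n))
        return th, 1.0 / H

    def test_zero_shift_is_identity(self):
        from coatfit.growth import linkage_sensitivity

        th, r = self._synthetic_sites()
        base = fit_growth_model(th, 1.0 / r, "CoopCM", "H")
        shifted = linkage_sensitivity(th, r, 0.0, observables=("H",))["H"]
        assert shifted.params_["H0"] == pytest.approx(base.params_["H0"], rel=1e-6)

    def test_shift_direction(self):
        from coatfit.growth import linkage_sensitivity

        th, r = self._synthetic_sites()
        minus = linkage_sensitivity(th, r, -10.0, observables=("H",))["H"]
        plus = linkage_sensitivity(th, r, +10.0, observables=("H",))["H"]
        base = fit_growth_model(th, 1.0 / r, "CoopCM", "H")
        assert minus.params_["H0"] > base.params_["H0"] > plus.params_["H0"]
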