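"""Compartment-model ODE system against closed-form and matrix-exponential oracles."""

import numpy as np
import pytest
from scipy.integrate import simpson
from scipy.linalg import expm

import gutflux as gf
from gutflux.model import initial_state, ode_rhs, system_matrix


def gp_closed_form(k: gf.RateConstants, P0: float, V: float, t: np.ndarray) -> np.ndarray:
    """Two-exponential absorption/elimination solution of the propionate branch."""
    alpha = k.k1p + k.k0p
    return k.k1p * P0 / (V * (k.k2 - alpha)) * (np.exp(-alpha * t) - np.exp(-k.k2 * t))


class TestRhs:
    def test_all_zero_rates_give_zero_derivative(self, subject):
        k = gf.RateConstants(0, 0, 0, 0, 0, 0, 0, 0)
        state = np.array([9.6, 1.0, 0.5, 4.0, 0.2, 0.9, 0.1])
        np.testing.assert_array_equal(ode_rhs(state, k, subject), np.zeros(7))

    def test_gut_uptake_and_loss_arithmetic(self, subject):
        k = gf.RateConstants(k1a=0.01, k1p=0, k1b=0, kLa=0, k2=0, k0a=0.02, k0p=0, k0b=0)
        state = np.array([9.6, 0, 0, 0, 0, 0, 0])
        d = ode_rhs(state, k, subject)
        assert d[0] == pytest.approx(-0.288)  # -(k1a+k0a)*A_gut
        assert d[1] == pytest.approx(0.096)  # k1a*A_gut

    def test_plasma_clearance_is_volume_independent(self):
        k = gf.RateConstants(0, 0, 0, 0, 0.02, 0, 0, 0)
        for bw in (50.0, 100.0):
            subj = gf.SubjectProfile(body_weight_kg=bw)
            state = np.zeros(7)
            state[4] = 1.0  # G_p = 1 mM
            assert ode_rhs(state, k, subj)[4] == pytest.approx(-0.02)

    def test_rejects_bad_state_and_volume(self, subject):
        k = gf.PAPER_REGIME_K
        with pytest.raises(ValueError):
            ode_rhs(np.zeros(5), k, subject)
        with pytest.raises(ValueError):
            system_matrix(k, 0.0)


class TestSimulate:
    def test_pure_loss_half_life(self, subject):
        k = gf.RateConstants(0, 0, 0, 0, 0, np.log(2) / 100, 0, 0)
        res = gf.simulate(k, gf.TracerDose(), subject, [100.0])
        assert res.states[-1, 0] == pytest.approx(4.8, abs=1e-6)

    def test_propionate_branch_matches_bateman_solution(self, regime_k, dose, subject, times):
        res = gf.simulate(regime_k, dose, subject, times)
        expected = gp_closed_form(regime_k, dose.P0, subject.v_plasma_L, times)
        np.testing.assert_allclose(
            res.curve("propionate").values, expected, atol=1e-7 * expected.max()
        )

    def test_full_system_matches_matrix_exponential(self, regime_k, dose, subject):
        A = system_matrix(regime_k, subject.v_plasma_L)
        y0 = initial_state(dose)
        times = np.array([5.0, 30.0, 90.0, 200.0])
        res = gf.simulate(regime_k, dose, subject, times)
        for i, t in enumerate(times):
            np.testing.assert_allclose(res.states[i], expm(A * t) @ y0, rtol=1e-6, atol=1e-10)

    def test_label_conservation_on_all_branches(self, regime_k, dose, subject):
        k, V = regime_k, subject.v_plasma_L
        t = np.linspace(0.0, 600.0, 1201)
        res = gf.simulate(regime_k, dose, subject, t)
        s = res.states
        branches = [
            # (dose, gut cols + liver, glucose col, k0)
            (dose.A0, s[:, 0], s[:, 1], s[:, 2], k.k0a),
            (dose.P0, s[:, 3], None, s[:, 4], k.k0p),
            (dose.B0, s[:, 5], None, s[:, 6], k.k0b),
        ]
        for total, gut, liver, g, k0 in branches:
            losses = simpson(k0 * gut, x=t)
            cleared = simpson(k.k2 * V * g, x=t)
            remaining = gut[-1] + (liver[-1] if liver is not None else 0.0) + V * g[-1]
            np.testing.assert_allclose(losses + cleared + remaining, total, rtol=1e-6)

    def test_curves_stay_non_negative_and_gut_decays(self, regime_k, dose, subject, times):
        res = gf.simulate(regime_k, dose, subject, times)
        assert np.all(res.states >= 0)
        for col in (0, 3, 5):
            assert np.all(np.diff(res.states[:, col]) <= 1e-12)

    def test_rejects_bad_times(self, regime_k, dose, subject):
        with pytest.raises(ValueError):
            gf.simulate(regime_k, dose, subject, [-10.0, 0.0])
        with pytest.raises(ValueError):
            gf.simulate(regime_k, dose, subject, [0.0, 0.0])
        with pytest.raises(ValueError):
            gf.simulate(regime_k, dose, subject, [])


class TestTypes:
    def test_dose_from_infusion_composition(self):
        d = gf.TracerDose.from_infusion((0.96, 0.40, 0.09), volume_mL=10.0)
        assert (d.A0, d.P0, d.B0) == pytest.approx((9.6, 4.0, 0.9), abs=1e-12)

    def test_plasma_volume_scaling(self):
        assert gf.SubjectProfile(body_weight_kg=80.0).v_plasma_L == pytest.approx(12.0)
        assert gf.SubjectProfile(body_weight_kg=80.0, v_plasma_L=10.0).v_plasma_L == 10.0

    def test_curve_validation(self):
        with pytest.raises(ValueError):
            gf.EnrichmentCurve([0, 1, 1], [0, 0, 0], "acetate")
        with pytest.raises(ValueError):
            gf.EnrichmentCurve([0, 1], [0, 0], "acetate", sd=[0.1, 0.0])
        with pytest.raises(ValueError):
            gf.RateConstants(-0.1, 0, 0, 0, 0, 0, 0, 0)
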