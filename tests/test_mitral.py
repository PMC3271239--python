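"""Dynamic mitral valve: impedance laws, flow equation, aperture oscillator."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from minicvs import (aperture_equilibrium, aperture_rhs, mitral_flow_rhs,
                     mitral_inertance, mitral_resistance, preset)
from minicvs.mitral_dynamics import (MMHG_S_PER_ML_IN_SI, aperture_gate,
                                     effective_inertance, effective_resistance)
from minicvs.parameters import MitralDynamicsParams


def params(**kw):
    base = dict(Ks=0.05, Amax=1.1, omega=30.0, D=10.0, dc=0.0,
                rho=1050.0, mu=4.0e-3, l=0.02, eps=1e-12)
    base.update(kw)
    return MitralDynamicsParams(**base)


class TestCylindricalImpedance:
    def test_resistance_unit_conversion_against_hand_oracle(self):
        # independent evaluation: 8*pi*mu*l/A^2 in SI, then converted
        p = params()
        a_m2 = 1.1e-4
        expected_si = 8.0 * math.pi * 4.0e-3 * 0.02 / a_m2 ** 2
        expected = expected_si / 1.33322e8
        assert mitral_resistance(1.1, p) == pytest.approx(expected, rel=1e-10)
        assert expected == pytest.approx(1.246e-3, rel=1e-3)

    def test_inertance_unit_conversion_against_hand_oracle(self):
        p = params()
        expected_si = 1050.0 * 0.02 / 1.1e-4
        expected = expected_si / 1.33322e8
        assert mitral_inertance(1.1, p) == pytest.approx(expected, rel=1e-10)
        assert expected == pytest.approx(1.432e-3, rel=1e-3)

    def test_inverse_square_and_inverse_scaling(self):
        p = params()
        assert mitral_resistance(0.5, p) / mitral_resistance(1.0, p) == \
            pytest.approx(4.0, rel=1e-9)
        assert mitral_inertance(0.5, p) / mitral_inertance(1.0, p) == \
            pytest.approx(2.0, rel=1e-9)

    def test_regularised_closed_limit_is_finite_and_large(self):
        p = params(eps=1e-4)
        r0 = mitral_resistance(0.0, p)
        assert math.isfinite(r0)
        assert r0 > 1e6 * mitral_resistance(1.1, p)

    def test_wide_open_inertance_vanishes(self):
        p = params()
        assert mitral_inertance(1e12, p) < 1e-12


class TestAnchoredImpedance:
    def test_matches_reference_values_at_reference_area(self):
        p = preset("healthy").mitral  # anchored law, A_ref = 1.1
        assert effective_resistance(1.1, p) == pytest.approx(0.0158, rel=1e-3)
        assert effective_inertance(1.1, p) == pytest.approx(7.6968e-5, rel=1e-3)

    def test_closure_defect_leak_resistance(self):
        p = preset("imi").mitral
        # R grows as (A_ref/A)^2: at the 0.2 cm^2 defect ~30x the open value
        assert effective_resistance(0.2, p) == pytest.approx(
            0.0158 * (1.1 / 0.2) ** 2, rel=1e-2)


class TestFlowEquation:
    def test_static_ohmic_equilibrium(self):
        p = params()
        r = effective_resistance(0.8, p)
        q_star = 5.0 / r
        assert mitral_flow_rhs(10.0, 5.0, q_star, 0.8, 0.0, p) == \
            pytest.approx(0.0, abs=1e-6)

    def test_rest_at_zero_gradient(self):
        p = params()
        assert mitral_flow_rhs(7.0, 7.0, 0.0, 0.5, 0.0, p) == 0.0

    def test_shrinking_area_decelerates_flow(self):
        p = params()
        static = mitral_flow_rhs(10.0, 5.0, 200.0, 0.8, 0.0, p)
        shrinking = mitral_flow_rhs(10.0, 5.0, 200.0, 0.8, -1.0, p)
        assert shrinking < static
        assert static - shrinking == pytest.approx(200.0 * 1.0 / (0.8 + p.eps),
                                                   rel=1e-9)


class TestApertureOscillator:
    def test_frozen_at_closure_defect_under_adverse_gradient(self):
        p = params(dc=0.2)
        assert aperture_rhs(5.0, 10.0, 0.2, 0.0, p) == (0.0, 0.0)
        assert aperture_gate(5.0, 10.0, 0.2, p) == 0.0

    def test_moving_above_defect_even_with_adverse_gradient(self):
        p = params(dc=0.2)
        dA, dAdot = aperture_rhs(5.0, 10.0, 0.5, -0.1, p)
        assert dA == -0.1 and dAdot != 0.0

    def test_equilibrium_closed_form_half_opening(self):
        # Ks*dP = 1 gives A* = Amax/2
        p = params(Ks=0.05)
        assert aperture_equilibrium(20.0, p) == pytest.approx(p.Amax / 2,
                                                              rel=1e-12)

    def test_equilibrium_below_amax_for_any_gradient(self):
        p = params()
        for dp in (0.1, 1.0, 10.0, 1e4):
            assert 0 < aperture_equilibrium(dp, p) < p.Amax

    def test_equilibrium_matches_clamped_gradient_integration(self):
        """Long integration under a clamped favourable gradient lands on
        Amax*Ks*dP/(1 + Ks*dP) to better than 1e-6 relative error."""
        p = params(Ks=0.05)
        dp = 20.0

        def rhs(t, y):
            return aperture_rhs(dp, 0.0, y[0], y[1], p)

        sol = solve_ivp(rhs, (0.0, 5.0), [0.3, 0.0], rtol=1e-10, atol=1e-12)
        a_inf = sol.y[0, -1]
        assert abs(a_inf - aperture_equilibrium(dp, p)) / a_inf < 1e-6

    def test_free_decay_matches_damped_oscillator_closed_form(self):
        """With the gradient clamped at zero and the valve off its floor,
        A(t) follows the underdamped free decay
        e^{-D t}(A0 cos wd t + (D A0 / wd) sin wd t), wd = sqrt(w^2 - D^2)."""
        p = params()
        a0 = 0.4
        wd = math.sqrt(p.omega ** 2 - p.D ** 2)

        def rhs(t, y):
            w = p.omega
            return [y[1], -2.0 * p.D * y[1] - w * w * y[0]]

        t_end = 0.05  # before the first zero crossing (gate stays open)
        sol = solve_ivp(rhs, (0.0, t_end), [a0, 0.0], rtol=1e-11, atol=1e-13,
                        dense_output=True)
        # same trajectory through the gated public operation
        def rhs_gated(t, y):
            return aperture_rhs(0.0, 0.0, y[0], y[1], p)

        solg = solve_ivp(rhs_gated, (0.0, t_end), [a0, 0.0], rtol=1e-11,
                         atol=1e-13)
        for t in (0.01, 0.03, t_end):
            expected = math.exp(-p.D * t) * (
                a0 * math.cos(wd * t) + p.D * a0 / wd * math.sin(wd * t))
            assert sol.sol(t)[0] == pytest.approx(expected, rel=1e-7)
        assert solg.y[0, -1] == pytest.approx(sol.y[0, -1], rel=1e-7)
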