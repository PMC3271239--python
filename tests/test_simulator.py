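"""Full-system right-hand side, integration, steady state, conservation."""

import math

import numpy as np
import pytest

import minicvs as m
from minicvs import simulator as sim
from minicvs.chambers import solve_ventricular_interaction
from minicvs.mitral_dynamics import mitral_flow_rhs, aperture_rhs
from minicvs.valves import heaviside, valve_flow_rhs
from minicvs.activation import driver


def reference_state(p):
    y = sim.initial_state(p)
    y[6:10] = [120.0, 80.0, 30.0, 55.0]   # all valves carrying flow
    if p.variant == "dynamic_mv":
        y[10], y[11] = 0.6, 0.4
    return y


class TestRHS:
    def test_volume_conservation_is_exact_pointwise(self):
        for variant in ("heaviside", "dynamic_mv"):
            p = m.preset("healthy")
            p.variant = variant
            rng = np.random.default_rng(7)
            for _ in range(20):
                y = reference_state(p)
                y[:6] *= rng.uniform(0.5, 1.5, 6)
                y[6:10] = rng.uniform(-50, 300, 4)
                d = m.rhs(rng.uniform(0, 1), y, p)
                assert abs(sum(d[:6])) < 1e-12

    def test_standstill_state_has_zero_derivative(self):
        """A state with every pressure equal and all flows zero is a
        fixed point: every gate is closed (H(0) = 0) and every
        derivative vanishes."""
        from scipy.optimize import brentq
        p = m.preset("healthy")
        p.numerics.interaction = False
        t, p_star, Pth = 0.0, 5.0, p.circ.Pth
        e = driver(t, p.driver)

        def ventricle_volume(chamber, vspt_sign):
            # free-wall volumes are Vlv - Vspt and Vrv + Vspt
            from minicvs.chambers import active_pressure
            return brentq(lambda v: active_pressure(v + vspt_sign * p.spt.Vd,
                                                    e, chamber)
                          + Pth - p_star, 0.0, 500.0)

        y = np.zeros(12)
        y[0] = (p_star - Pth) / p.pu.E
        y[1] = ventricle_volume(p.lvf, -1.0)
        y[2] = p_star / p.ao.E
        y[3] = p_star / p.vc.E
        y[4] = ventricle_volume(p.rvf, +1.0)
        y[5] = (p_star - Pth) / p.pa.E
        d = m.rhs(t, y, p)
        assert np.allclose(d, 0.0, atol=1e-7)

    def test_rhs_matches_hand_composition(self):
        """One evaluation of the assembled derivative equals composing the
        chamber, valve and mitral operations by hand."""
        p = m.preset("healthy")
        y = reference_state(p)
        t = 0.31
        d = m.rhs(t, y, p)

        e = driver(t, p.driver)
        vi = solve_ventricular_interaction(y[1], y[4], e, p)
        Pth = p.circ.Pth
        Ppu = p.pu.E * y[0] + Pth
        Ppa = p.pa.E * y[5] + Pth
        Pao = p.ao.E * y[2]
        Pvc = p.vc.E * y[3]
        qsys = max((Pao - Pvc) / p.circ.Rsys, 0.0)
        qpul = max((Ppa - Ppu) / p.circ.Rpul, 0.0)
        assert d[6] == pytest.approx(
            mitral_flow_rhs(Ppu, vi.Plv, y[6], y[10], y[11], p.mitral), rel=1e-9)
        assert d[7] == pytest.approx(
            valve_flow_rhs(vi.Plv, Pao, y[7], p.valves["av"]), rel=1e-9)
        assert d[1] == pytest.approx(y[6] - heaviside(y[7]) * y[7], rel=1e-9)
        assert d[2] == pytest.approx(heaviside(y[7]) * y[7] - qsys, rel=1e-9)
        dA, dAdot = aperture_rhs(Ppu, vi.Plv, y[10], y[11], p.mitral)
        assert d[10] == pytest.approx(dA, rel=1e-9)
        assert d[11] == pytest.approx(dAdot, rel=1e-9)


class TestSimulate:
    def test_total_volume_conserved_over_run(self, healthy_dyn):
        tv = healthy_dyn.total_volume()
        assert tv.max() - tv.min() < 1e-6

    def test_output_grid_is_uniform_and_cycle_local(self, healthy_dyn):
        t = healthy_dyn.t
        assert t[0] == 0.0
        assert t[-1] == pytest.approx(1.0)
        assert np.allclose(np.diff(t), 1e-3, atol=1e-9)

    def test_infinite_tolerance_returns_after_one_cycle(self):
        p = m.preset("healthy")
        res = m.run_to_steady_state(p, tol=math.inf, max_cycles=5)
        assert res.meta["cycles"] <= 2
        assert res.t[-1] == pytest.approx(p.driver.D1)

    def test_healthy_converges_quickly_from_default_state(self):
        p = m.preset("healthy")
        res = m.run_to_steady_state(p, tol=1e-3, max_cycles=20)
        assert res.meta["converged"]
        assert res.meta["cycles"] <= 20

    def test_periodicity_of_converged_cycle(self, healthy_dyn):
        starts = np.asarray(healthy_dyn.meta["cycle_starts"])
        y0, y1 = starts[-2], starts[-1]
        rel = np.abs(y1 - y0) / np.maximum(np.abs(y0), 1.0)
        assert rel.max() < 1e-3

    def test_imi_converges_without_volume_drift(self, imi_dyn):
        starts = np.asarray(imi_dyn.meta["cycle_starts"])
        totals = starts[:, :6].sum(axis=1)
        assert np.ptp(totals) < 1e-6

    def test_nonconvergence_raises_with_metric(self):
        p = m.preset("healthy")
        with pytest.raises(sim.SimulationError, match="change"):
            m.run_to_steady_state(p, tol=1e-14, max_cycles=2)


class TestRobustness:
    def test_steady_state_insensitive_to_initial_distribution(self, healthy_dyn):
        """Shuffling stressed volume between chambers (same total) leaves
        the converged cycle's metrics unchanged."""
        p = m.preset("healthy")
        p.init.Vpu -= 120.0
        p.init.Vvc += 80.0
        p.init.Vao += 40.0
        res = m.run_to_steady_state(p, max_cycles=120)
        met = m.cycle_metrics(res)
        ref = m.cycle_metrics(healthy_dyn)
        assert met.SV == pytest.approx(ref.SV, rel=5e-3)
        assert met.Vmin == pytest.approx(ref.Vmin, rel=5e-3)

    def test_metrics_stable_under_tolerance_halving(self, healthy_dyn):
        p = m.preset("healthy")
        p.numerics.rtol /= 2
        p.numerics.atol /= 2
        res = m.run_to_steady_state(p)
        met = m.cycle_metrics(res)
        ref = m.cycle_metrics(healthy_dyn)
        assert met.SV == pytest.approx(ref.SV, rel=5e-3)
        assert met.Qmt_max == pytest.approx(ref.Qmt_max, rel=5e-3)
        assert abs(met.t_open - ref.t_open) < 1e-3
        assert abs(met.t_close - ref.t_close) < 1e-3

    def test_smooth_gate_fallback_reproduces_global_hemodynamics(self, healthy_dyn):
        """The logistic-gate mode is a qualitative fallback: same stroke
        volume to ~2%, conserved volume; its gate boundaries deviate from
        the exact H(0) = 0 law by construction."""
        p = m.preset("healthy")
        p.numerics.gate_mode = "smooth"
        res = m.run_to_steady_state(p, tol=1e-3, max_cycles=60)
        tv = res.total_volume()
        assert tv.max() - tv.min() < 1e-3
        assert m.cycle_metrics(res).SV == pytest.approx(
            m.cycle_metrics(healthy_dyn).SV, rel=0.02)

    def test_stiffer_valve_shortens_opening_lag(self, healthy_dyn):
        """Raising the aperture's natural frequency tenfold shrinks the lag
        between the pressure crossover and the opening detected on A."""
        import dataclasses
        p = m.preset("healthy")
        p.mitral = dataclasses.replace(p.mitral, omega=300.0, D=100.0)
        res = m.run_to_steady_state(p, max_cycles=120)
        ref = m.cycle_metrics(healthy_dyn)
        met = m.cycle_metrics(res)

        def crossover(r):
            dp = r["Ppu"] - r["Plv"]
            t = r.t
            k = np.nonzero((dp[:-1] <= 0) & (dp[1:] > 0) & (t[:-1] > 0.3))[0]
            return t[k[0]]

        lag_ref = ref.t_open - crossover(healthy_dyn)
        lag_stiff = met.t_open - crossover(res)
        assert lag_stiff <= lag_ref + 1e-6
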