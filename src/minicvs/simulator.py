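"""Closed-loop assembly and time integration of the six-chamber model.

Two variants of the full system are integrated:

``heaviside``
    the baseline model — all four valves are inertial diodes under the
    "open on pressure, close on flow" Heaviside law;
``dynamic_mv``
    the extended model — the mitral valve carries the forced-oscillator
    aperture dynamics and an area-dependent impedance, with the
    transmitral flow equation ungated (regurgitation possible); the
    other three valves keep the Heaviside law.

State vector (clinical units)::

    [Vpu, Vlv, Vao, Vvc, Vrv, Vpa, Qmt, Qav, Qtc, Qpv]          baseline
    [...,                                          A, Adot]      extended

Integration strategy
--------------------
The Heaviside gates make the right-hand side discontinuous, and an
instantaneous gate H(Q) freezes flow exactly at Q = 0 — a boundary an
adaptive solver cannot step across (it chatters with ever-smaller
steps).  The default ``discrete`` mode therefore treats each gated
valve as a hybrid automaton: the gate state is held constant between
events, a closed valve reopens at an upward zero-crossing of its
pressure gradient, an open valve closes at a downward zero-crossing of
its flow (flow clamped to exactly zero there), and the stiff adaptive
integrator (LSODA) is restarted at every event.  In the extended
variant one further event clamps the mitral aperture on its floor
(A = dc) when it lands there under an adverse gradient.

The ``smooth`` fallback mode replaces every Heaviside by a logistic of
steepness ``k_smooth`` and integrates without events; it deviates from
H(0) = 0 at gate boundaries by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .activation import driver
from .chambers import solve_ventricular_interaction
from .mitral_dynamics import (aperture_rhs, effective_inertance,
                              effective_resistance, mitral_flow_rhs)
from .parameters import ModelParameters
from .valves import heaviside, smooth_heaviside, valve_flow_rhs, valve_gate

__all__ = [
    "STATE_NAMES_BASE",
    "STATE_NAMES_EXT",
    "state_names",
    "initial_state",
    "rhs",
    "SimulationResult",
    "simulate",
    "run_to_steady_state",
    "SimulationError",
]

STATE_NAMES_BASE = ("Vpu", "Vlv", "Vao", "Vvc", "Vrv", "Vpa",
                    "Qmt", "Qav", "Qtc", "Qpv")
STATE_NAMES_EXT = STATE_NAMES_BASE + ("A", "Adot")

DERIVED_NAMES = ("Plv", "Prv", "Ppu", "Ppa", "Pao", "Pvc", "Pperi", "Vspt",
                 "e", "Qsys", "Qpul", "Rmt", "Lmt")

class SimulationError(RuntimeError):
    pass


def state_names(variant: str):
    return STATE_NAMES_EXT if variant == "dynamic_mv" else STATE_NAMES_BASE


def initial_state(p: ModelParameters) -> np.ndarray:
    """Default initial state: configured volumes, zero flows, valve closed."""
    v = p.init
    y = [v.Vpu, v.Vlv, v.Vao, v.Vvc, v.Vrv, v.Vpa, 0.0, 0.0, 0.0, 0.0]
    if p.variant == "dynamic_mv":
        y += [p.mitral.dc, 0.0]
    return np.asarray(y, dtype=float)


# index of each inertial valve's flow in the state vector and its
# (upstream, downstream) pressure pair
_VALVE_INDEX = {"mt": 6, "av": 7, "tc": 8, "pv": 9}


class _System:
    """Pressures, flows and the full derivative at a state (shared code)."""

    def __init__(self, p: ModelParameters):
        self.p = p
        self.extended = p.variant == "dynamic_mv"
        self._vspt = p.spt.Vd
        self._memo_key = None
        self._memo_val = None

    def pressures(self, t, y):
        """(Plv, Prv, Ppu, Ppa, Pao, Pvc), memoised on (t, id-ish key)."""
        key = (t, y[1], y[4], y[0], y[5], y[2], y[3])
        if key == self._memo_key:
            return self._memo_val
        p = self.p
        e = driver(t, p.driver)
        try:
            vi = solve_ventricular_interaction(y[1], y[4], e, p, x0=self._vspt)
        except Exception as exc:
            raise SimulationError(
                f"ventricular interaction solve failed at t={t:.6f}s, "
                f"state={np.asarray(y).tolist()}") from exc
        self._vspt = vi.Vspt
        Pth = p.circ.Pth
        val = (vi.Plv, vi.Prv,
               p.pu.E * y[0] + (Pth if p.pu.thoracic else 0.0),
               p.pa.E * y[5] + (Pth if p.pa.thoracic else 0.0),
               p.ao.E * y[2] + (Pth if p.ao.thoracic else 0.0),
               p.vc.E * y[3] + (Pth if p.vc.thoracic else 0.0))
        self._memo_key = key
        self._memo_val = val
        return val

    def gradients(self, t, y):
        """Pressure gradient across each inertial valve, keyed by name."""
        Plv, Prv, Ppu, Ppa, Pao, Pvc = self.pressures(t, y)
        return {"mt": Ppu - Plv, "av": Plv - Pao,
                "tc": Pvc - Prv, "pv": Prv - Ppa}


class _HybridSystem(_System):
    """Discrete-gate system: gate booleans held constant between events."""

    def __init__(self, p: ModelParameters):
        super().__init__(p)
        self.gated = ["av", "tc", "pv"] if self.extended else ["mt", "av", "tc", "pv"]
        self.open: dict[str, bool] = {}
        self.mv_floored = False
        self.n_events = 0

    def prime(self, t0, y):
        """Initialise gate states from an instantaneous-gate snapshot."""
        g = self.gradients(t0, y)
        for v in self.gated:
            self.open[v] = valve_gate(g[v], 0.0, y[_VALVE_INDEX[v]]) > 0.0
        if self.extended:
            self.mv_floored = (y[10] <= self.p.mitral.dc + 1e-12
                               and g["mt"] <= 0.0)

    def f(self, t, y):
        p = self.p
        Plv, Prv, Ppu, Ppa, Pao, Pvc = self.pressures(t, y)
        Qmt, Qav, Qtc, Qpv = y[6], y[7], y[8], y[9]
        Qsys = (Pao - Pvc) / p.circ.Rsys
        Qpul = (Ppa - Ppu) / p.circ.Rpul
        grads = {"mt": Ppu - Plv, "av": Plv - Pao,
                 "tc": Pvc - Prv, "pv": Prv - Ppa}

        dQ = {}
        for v in self.gated:
            pv_ = p.valves[v]
            q = y[_VALVE_INDEX[v]]
            dQ[v] = (grads[v] - q * pv_.R) / pv_.L if self.open[v] else 0.0

        qav = Qav if (self.open.get("av") and Qav > 0.0) else 0.0
        qtc = Qtc if (self.open.get("tc") and Qtc > 0.0) else 0.0
        qpv = Qpv if (self.open.get("pv") and Qpv > 0.0) else 0.0
        qsys = Qsys if Qsys > 0.0 else 0.0
        qpul = Qpul if Qpul > 0.0 else 0.0

        if self.extended:
            A, Adot = y[10], y[11]
            dQmt = mitral_flow_rhs(Ppu, Plv, Qmt, A, Adot, p.mitral)
            if self.mv_floored:
                # the gate H(H(Ppu−Plv)+H(A−dc)−0.5) is held at 0
                # between events, exactly like the diode-valve gates
                dA, dAdot = 0.0, 0.0
            else:
                w = p.mitral.omega
                dA = Adot
                dAdot = (w * w * (p.mitral.Amax - A) * p.mitral.Ks * (Ppu - Plv)
                         - 2.0 * p.mitral.D * Adot - w * w * A)
            dVpu = qpul - Qmt
            dVlv = Qmt - qav
        else:
            dQmt = dQ["mt"]
            qmt = Qmt if (self.open["mt"] and Qmt > 0.0) else 0.0
            dVpu = qpul - qmt
            dVlv = qmt - qav
        out = [dVpu, dVlv, qav - qsys, qsys - qtc, qtc - qpv, qpv - qpul,
               dQmt, dQ["av"], dQ["tc"], dQ["pv"]]
        if self.extended:
            out += [dA, dAdot]
        return out

    # -- events -----------------------------------------------------------

    def events(self):
        """Event list for the *current* gate configuration.

        Rebuilt after every switch: a closed valve watches for an
        upward zero-crossing of its pressure gradient ("open on
        pressure"), an open valve for a downward zero-crossing of its
        flow ("close on flow"); the aperture-floor event is armed only
        while the aperture is descending, so a valve frozen on its
        floor cannot retrigger it.
        """
        evs = [self._closing_event(v) if self.open[v] else self._opening_event(v)
               for v in self.gated]
        if self.extended:
            if self.mv_floored:
                evs.append(self._liftoff_event())
            else:
                evs.append(self._floor_event())
                evs.append(self._ceiling_event())
                if self.p.mitral.dc > 0.0:
                    evs.append(self._zero_event())
                    evs.append(self._freeze_event())
        return evs

    def _closing_event(self, v):
        idx = _VALVE_INDEX[v]

        def ev(t, y):
            return y[idx]
        ev.terminal = True
        ev.direction = -1.0
        ev._name = v
        return ev

    def _opening_event(self, v):
        def ev(t, y):
            return self.gradients(t, y)[v]
        ev.terminal = True
        ev.direction = 1.0
        ev._name = v
        return ev

    def _floor_event(self):
        # aperture reaches its floor (0 healthy, dc in IMI) from above
        dc = self.p.mitral.dc

        def ev(t, y):
            return y[10] - dc
        ev.terminal = True
        ev.direction = -1.0
        ev._name = "_floor"
        return ev

    def _zero_event(self):
        # hard anatomical floor A = 0 (reachable below dc in IMI when a
        # favourable gradient lets the aperture pass the closure defect)
        def ev(t, y):
            return y[10]
        ev.terminal = True
        ev.direction = -1.0
        ev._name = "_zero"
        return ev

    # gradient hysteresis half-band (mmHg): freeze/liftoff fire a hair
    # past zero so root-finder noise in the septum solve cannot make
    # the pair chatter while the gradient hovers at zero in diastasis
    _GRAD_BAND = 1.0e-6

    def _freeze_event(self):
        # IMI, aperture below the closure defect: an adverse gradient
        # freezes it in place (the literal composite-gate behaviour)
        dc = self.p.mitral.dc
        band = self._GRAD_BAND

        def ev(t, y):
            return (self.gradients(t, y)["mt"] + band) if y[10] < dc else 1.0
        ev.terminal = True
        ev.direction = -1.0
        ev._name = "_freeze"
        return ev

    def _ceiling_event(self):
        # the aperture cannot exceed the maximal anatomical area: the
        # leaflets lose their kinetic energy at the annulus limit
        Amax = self.p.mitral.Amax

        def ev(t, y):
            return y[10] - Amax
        ev.terminal = True
        ev.direction = 1.0
        ev._name = "_ceiling"
        return ev

    def _liftoff_event(self):
        # floored aperture resumes moving when the gradient turns
        band = self._GRAD_BAND

        def ev(t, y):
            return self.gradients(t, y)["mt"] - band
        ev.terminal = True
        ev.direction = 1.0
        ev._name = "_liftoff"
        return ev

    def handle_event(self, name, t_ev, y_ev, t1):
        """Apply a gate switch; returns the new (t, state)."""
        self.n_events += 1
        y = y_ev.copy()
        if name == "_zero":
            # the aperture cannot open negatively: clamp; freeze unless
            # a favourable gradient relaunches it at once
            y[10] = 0.0
            y[11] = 0.0
            self.mv_floored = self.gradients(t_ev, y)["mt"] <= 0.0
        elif name == "_floor":
            dc = self.p.mitral.dc
            if self.gradients(t_ev, y)["mt"] <= 0.0:
                y[10] = dc
                y[11] = 0.0
                self.mv_floored = True
            elif dc == 0.0:
                y[10] = 0.0
                y[11] = 0.0
            else:
                # IMI with favourable gradient: the aperture may dip
                # below the closure defect; nudge past the crossing so
                # the event cannot refire in place
                h = min(1e-7, t1 - t_ev)
                y = y + h * np.asarray(self.f(t_ev, y))
                t_ev = t_ev + h
        elif name == "_ceiling":
            y[10] = self.p.mitral.Amax
            y[11] = 0.0
        elif name == "_freeze":
            y[11] = 0.0
            self.mv_floored = True
        elif name == "_liftoff":
            self.mv_floored = False
        elif self.open[name]:
            self.open[name] = False
            y[_VALVE_INDEX[name]] = 0.0
        else:
            self.open[name] = True
        return t_ev, y


class _SmoothSystem(_System):
    """Logistic-gate system: differentiable RHS, no events."""

    def prime(self, t0, y):
        pass

    def events(self):
        return []

    def f(self, t, y):
        p = self.p
        k = p.numerics.k_smooth
        H = lambda x: smooth_heaviside(x, k)
        Plv, Prv, Ppu, Ppa, Pao, Pvc = self.pressures(t, y)
        Qmt, Qav, Qtc, Qpv = y[6], y[7], y[8], y[9]
        Qsys = (Pao - Pvc) / p.circ.Rsys
        Qpul = (Ppa - Ppu) / p.circ.Rpul
        dQav = valve_flow_rhs(Plv, Pao, Qav, p.valves["av"], mode="smooth", k=k)
        dQtc = valve_flow_rhs(Pvc, Prv, Qtc, p.valves["tc"], mode="smooth", k=k)
        dQpv = valve_flow_rhs(Prv, Ppa, Qpv, p.valves["pv"], mode="smooth", k=k)
        qav, qtc, qpv = H(Qav) * Qav, H(Qtc) * Qtc, H(Qpv) * Qpv
        qsys, qpul = H(Qsys) * Qsys, H(Qpul) * Qpul
        if self.extended:
            A, Adot = y[10], y[11]
            dQmt = mitral_flow_rhs(Ppu, Plv, Qmt, A, Adot, p.mitral)
            g = H(H(Ppu - Plv) + H(A - p.mitral.dc) - 0.5)
            w = p.mitral.omega
            dA = g * Adot
            dAdot = g * (w * w * (p.mitral.Amax - A) * p.mitral.Ks * (Ppu - Plv)
                         - 2.0 * p.mitral.D * w * Adot - w * w * A)
            dVpu = qpul - Qmt
            dVlv = Qmt - qav
        else:
            dQmt = valve_flow_rhs(Ppu, Plv, Qmt, p.valves["mt"], mode="smooth", k=k)
            qmt = H(Qmt) * Qmt
            dVpu = qpul - qmt
            dVlv = qmt - qav
        out = [dVpu, dVlv, qav - qsys, qsys - qtc, qtc - qpv, qpv - qpul,
               dQmt, dQav, dQtc, dQpv]
        if self.extended:
            out += [dA, dAdot]
        return out

    def handle_event(self, name, t_ev, y_ev, t1):  # pragma: no cover
        return t_ev, y_ev


def _make_system(p: ModelParameters) -> _System:
    if p.numerics.gate_mode == "smooth":
        return _SmoothSystem(p)
    return _HybridSystem(p)


def rhs(t: float, y, p: ModelParameters):
    """One evaluation of the full model derivative (public, stateless).

    Gates are evaluated instantaneously from the supplied state (no
    hysteresis memory), exactly as the composite Heaviside expressions
    read.
    """
    p.validate()
    y = np.asarray(y, dtype=float)
    if p.numerics.gate_mode == "smooth":
        sys_ = _SmoothSystem(p)
        return np.asarray(sys_.f(t, y))
    sys_ = _HybridSystem(p)
    sys_.prime(t, y)
    return np.asarray(sys_.f(t, y))


def _integrate_cycle(sys_: _System, t0, t1, y0, t_eval):
    """Integrate [t0, t1] restarting at every gate event.

    ``t_eval`` must be either empty or a grid whose last point is t1.
    Returns (ts, ys, y_end).
    """
    num = sys_.p.numerics
    extended = sys_.extended
    ts, ys = [], []
    t_start, y = t0, np.asarray(y0, dtype=float)
    n_seg = 0
    while True:
        if extended and y[10] < 0.0:
            # roundoff guard: the aperture may not rest below its floor
            y[10] = 0.0
            if y[11] < 0.0:
                y[11] = 0.0
        events = sys_.events()
        if t_eval.size:
            lo = t_start - 1e-12 if n_seg == 0 else t_start + 1e-12
            sel = t_eval[(t_eval > lo) & (t_eval <= t1 + 1e-12)]
        else:
            sel = t_eval
        try:
            sol = solve_ivp(sys_.f, (t_start, t1), y, method="LSODA",
                            t_eval=sel if sel.size else None,
                            events=events, rtol=num.rtol, atol=num.atol,
                            max_step=num.max_step)
        except ValueError as exc:
            if "different signs" not in str(exc):
                raise
            # an event function is numerically degenerate (|g| at
            # roundoff scale on both sides): hop a few microseconds
            # past the point with events disabled and resume
            hop = solve_ivp(sys_.f, (t_start, min(t_start + 1e-5, t1)), y,
                            method="LSODA", rtol=num.rtol, atol=num.atol,
                            max_step=num.max_step)
            t_start = float(hop.t[-1])
            y = hop.y[:, -1]
            n_seg += 1
            if n_seg > 1000:
                raise SimulationError(
                    f"event loop did not terminate near t={t_start:.6f}s")
            if t_start >= t1 - 1e-12:
                break
            continue
        if sol.status < 0:
            raise SimulationError(
                f"integration failed at "
                f"t={sol.t[-1] if sol.t.size else t_start:.6f}s: {sol.message}")
        if sel.size and len(sol.t):
            ts.extend(sol.t)
            ys.extend(sol.y.T)
        if sol.status == 1:
            hits = [(te[0], i) for i, te in enumerate(sol.t_events) if te.size]
            t_ev, i_ev = min(hits)
            y_ev = sol.y_events[i_ev][0]
            t_ev, y = sys_.handle_event(events[i_ev]._name, float(t_ev), y_ev, t1)
            n_seg += 1
            if n_seg > 1000:
                raise SimulationError(
                    f"event loop did not terminate near t={t_ev:.6f}s")
            if t_ev >= t1 - 1e-12:
                break
            t_start = float(t_ev)
            continue
        # reached t1: with a (t1-terminated) grid the last sample is the
        # end state; without a grid solve_ivp's own last step is at t1
        y = np.asarray(ys[-1] if sel.size else sol.y[:, -1], dtype=float)
        break
    return np.asarray(ts), np.asarray(ys), np.asarray(y, dtype=float)


def _derived_row(t, y, p, cache):
    e = driver(t, p.driver)
    vi = solve_ventricular_interaction(y[1], y[4], e, p, x0=cache.get("Vspt"))
    cache["Vspt"] = vi.Vspt
    Pth = p.circ.Pth
    Ppu = p.pu.E * y[0] + (Pth if p.pu.thoracic else 0.0)
    Ppa = p.pa.E * y[5] + (Pth if p.pa.thoracic else 0.0)
    Pao = p.ao.E * y[2] + (Pth if p.ao.thoracic else 0.0)
    Pvc = p.vc.E * y[3] + (Pth if p.vc.thoracic else 0.0)
    if p.variant == "dynamic_mv":
        Rmt = effective_resistance(y[10], p.mitral)
        Lmt = effective_inertance(y[10], p.mitral)
    else:
        Rmt, Lmt = p.valves["mt"].R, p.valves["mt"].L
    return (vi.Plv, vi.Prv, Ppu, Ppa, Pao, Pvc, vi.Pperi, vi.Vspt, e,
            (Pao - Pvc) / p.circ.Rsys, (Ppa - Ppu) / p.circ.Rpul, Rmt, Lmt)


@dataclass
class SimulationResult:
    """Dense trajectory of one run: states plus derived hemodynamics.

    ``data`` holds one row per output sample with a ``t`` column, all
    state columns and all derived columns; ``meta`` records preset,
    variant, solver settings, cycles simulated and the convergence
    metric history.
    """

    data: pd.DataFrame
    meta: dict = field(default_factory=dict)

    @property
    def t(self) -> np.ndarray:
        return self.data["t"].to_numpy()

    def __getitem__(self, key: str) -> np.ndarray:
        return self.data[key].to_numpy()

    @property
    def variant(self) -> str:
        return self.meta.get("variant", "unknown")

    def total_volume(self) -> np.ndarray:
        return sum(self[k] for k in ("Vpu", "Vlv", "Vao", "Vvc", "Vrv", "Vpa"))


def _build_result(ts, ys, p, meta) -> SimulationResult:
    names = state_names(p.variant)
    cols = {"t": ts}
    for i, nm in enumerate(names):
        cols[nm] = ys[:, i]
    cache = {}
    derived = np.array([_derived_row(t, y, p, cache) for t, y in zip(ts, ys)])
    for i, nm in enumerate(DERIVED_NAMES):
        cols[nm] = derived[:, i]
    meta = dict(meta)
    meta.update(variant=p.variant, preset=p.preset_name,
                mitral={"dc": p.mitral.dc, "eps": p.mitral.eps,
                        "Amax": p.mitral.Amax},
                solver={"method": "LSODA", "rtol": p.numerics.rtol,
                        "atol": p.numerics.atol, "max_step": p.numerics.max_step,
                        "gate_mode": p.numerics.gate_mode},
                dt_out=p.numerics.dt_out, D1=p.driver.D1)
    return SimulationResult(data=pd.DataFrame(cols), meta=meta)


def _cycle_change(y0, y1):
    """Max component-wise relative change between successive cycle starts."""
    return float(np.max(np.abs(np.asarray(y1) - np.asarray(y0))
                        / np.maximum(np.abs(np.asarray(y0)), 1.0)))


def simulate(p: ModelParameters, n_cycles: int = 1,
             dt_out: float | None = None,
             y0: np.ndarray | None = None) -> SimulationResult:
    """Integrate ``n_cycles`` cardiac periods from the initial state.

    Returns the dense trajectory over all cycles on a fixed dt_out
    grid; ``meta['cycle_starts']`` holds the state at every cycle
    boundary and ``meta['cycle_changes']`` the per-cycle convergence
    metric.
    """
    p.validate()
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    dt = p.numerics.dt_out if dt_out is None else dt_out
    D1 = p.driver.D1
    sys_ = _make_system(p)
    y = initial_state(p) if y0 is None else np.asarray(y0, dtype=float)
    sys_.prime(0.0, y)
    all_t, all_y = [], []
    starts, changes = [y.copy()], []
    n_per = int(round(D1 / dt))
    for c in range(n_cycles):
        t0, t1 = c * D1, (c + 1) * D1
        t_eval = t0 + np.arange(n_per + 1) * dt
        ts, ys, y_end = _integrate_cycle(sys_, t0, t1, y, t_eval)
        if c < n_cycles - 1:  # drop duplicated cycle-boundary sample
            ts, ys = ts[:-1], ys[:-1]
        all_t.append(ts)
        all_y.append(ys)
        changes.append(_cycle_change(y, y_end))
        y = y_end
        starts.append(y.copy())
    ts = np.concatenate(all_t)
    ys = np.concatenate(all_y)
    meta = {"cycles": n_cycles,
            "cycle_starts": [s.tolist() for s in starts],
            "cycle_changes": changes,
            "n_events": getattr(sys_, "n_events", 0),
            "converged": changes[-1] < p.numerics.ss_tol}
    return _build_result(ts, ys, p, meta)


def run_to_steady_state(p: ModelParameters, tol: float | None = None,
                        max_cycles: int | None = None,
                        dt_out: float | None = None) -> SimulationResult:
    """Cycle until the state at successive cycle starts is periodic.

    Repeats cardiac cycles until the maximum component-wise relative
    change between consecutive cycle-start states falls below ``tol``
    (numerics.ss_tol by default), then returns one further full cycle
    on a dense cycle-local time grid.  Raises SimulationError with the
    achieved metric on non-convergence.
    """
    p.validate()
    tol = p.numerics.ss_tol if tol is None else tol
    max_cycles = p.numerics.max_cycles if max_cycles is None else max_cycles
    dt = p.numerics.dt_out if dt_out is None else dt_out
    D1 = p.driver.D1
    sys_ = _make_system(p)
    y = initial_state(p)
    sys_.prime(0.0, y)
    starts, changes = [y.copy()], []
    empty = np.asarray([])
    converged = math.isinf(tol)
    n_used = 0
    for c in range(max_cycles):
        t0, t1 = c * D1, (c + 1) * D1
        _, _, y_end = _integrate_cycle(sys_, t0, t1, y, empty)
        change = _cycle_change(y, y_end)
        changes.append(change)
        y = y_end
        starts.append(y.copy())
        n_used = c + 1
        if change < tol:
            converged = True
            break
    if not converged:
        raise SimulationError(
            f"no periodic steady state within {max_cycles} cycles "
            f"(last cycle-to-cycle change {changes[-1]:.3e} > tol {tol:.3e})")
    # one more full cycle, densely sampled, reported in cycle-local time
    t0, t1 = n_used * D1, (n_used + 1) * D1
    n_per = int(round(D1 / dt))
    t_eval = t0 + np.arange(n_per + 1) * dt
    ts, ys, y_end = _integrate_cycle(sys_, t0, t1, y, t_eval)
    starts.append(y_end.copy())
    changes.append(_cycle_change(y, y_end))
    meta = {"cycles": n_used + 1,
            "cycle_starts": [s.tolist() for s in starts],
            "cycle_changes": changes,
            "n_events": getattr(sys_, "n_events", 0),
            "converged": True,
            "ss_tol": tol}
    return _build_result(ts - t0, ys, p, meta)
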