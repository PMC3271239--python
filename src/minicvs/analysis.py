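"""Cycle metrics: PV-loop corners, valve timing, flows, volumes.

All operations are pure functions of a one-cycle :class:`SimulationResult`
(states and derived hemodynamics on a dense, fixed-step time grid) and
report times in cycle-local coordinates, i.e. in the driver's phase
frame (peak activation at t = C1).

Event instants are located by linear interpolation between output
samples, so their resolution is well below the output step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .simulator import SimulationResult

__all__ = [
    "MitralTiming",
    "Corner",
    "CycleMetrics",
    "valve_timing",
    "pv_corners",
    "cycle_metrics",
    "compare_variants",
]

#: volume change (ml) above which an "isovolumetric" phase is flagged absent
ISOVOLUMETRIC_TOL = 1.0


def _interp_crossing(t0, t1, x0, x1, thr):
    if x1 == x0:
        return t0
    return t0 + (thr - x0) * (t1 - t0) / (x1 - x0)


def _upcrossings(t, x, thr):
    i = np.nonzero((x[:-1] <= thr) & (x[1:] > thr))[0]
    return [_interp_crossing(t[k], t[k + 1], x[k], x[k + 1], thr) for k in i]


def _downcrossings(t, x, thr):
    i = np.nonzero((x[:-1] > thr) & (x[1:] <= thr))[0]
    return [_interp_crossing(t[k], t[k + 1], x[k], x[k + 1], thr) for k in i]


def _at(t, x, ti):
    return float(np.interp(ti, t, x))


@dataclass
class MitralTiming:
    """Mitral opening/peak/closing instants within the cycle (s)."""

    opened: bool
    t_open: float = math.nan
    t_peak: float = math.nan
    t_close: float = math.nan

    @property
    def open_duration(self) -> float:
        return self.t_close - self.t_open


def valve_timing(result: SimulationResult,
                 area_threshold: float | None = None) -> MitralTiming:
    """Opening, peak-area and closing times from the aperture trace.

    ``area_threshold`` defaults to dc + eps: the regularisation floor
    for a healthy valve, and the same margin above the closure defect
    for an insufficient one (which never reaches zero).  A trace that
    never exceeds the threshold yields ``opened = False`` rather than
    an error.
    """
    if "A" not in result.data.columns:
        raise ValueError("result has no aperture trace 'A' "
                         "(baseline-variant run?)")
    t = result.t
    A = result["A"]
    if area_threshold is None:
        m = result.meta.get("mitral", {})
        area_threshold = m.get("dc", 0.0) + m.get("eps", 1e-4)
    ups = _upcrossings(t, A, area_threshold)
    if not ups:
        return MitralTiming(opened=False)
    t_open = ups[0]
    k = int(np.argmax(A))
    t_peak = float(t[k])
    downs = [d for d in _downcrossings(t, A, area_threshold) if d > t_peak]
    t_close = downs[0] if downs else float(t[-1])
    return MitralTiming(opened=True, t_open=float(t_open),
                        t_peak=t_peak, t_close=float(t_close))


@dataclass
class Corner:
    """One PV-loop corner: LV pressure/volume at a valve event instant."""

    P: float
    V: float
    t: float
    flag: str = "ok"


def _flow_threshold(Q):
    return max(1e-9, 1e-4 * float(np.max(np.abs(Q), initial=0.0)))


def pv_corners(result: SimulationResult) -> list:
    """The four PV-loop corners of the left ventricle.

    corner 1: end diastole (mitral inflow ends — last fall of Qmt);
    corner 2: aortic opening (Qav first becomes positive);
    corner 3: end systole (aortic flow ends);
    corner 4: mitral opening (Qmt first becomes positive).

    When a valve event cannot be located its corner is flagged
    ``not_detected``; when the volume change across a nominally
    isovolumetric phase exceeds ISOVOLUMETRIC_TOL the bounding corners
    are flagged (the phase has disappeared, as under mitral
    insufficiency) but still reported.
    """
    t = result.t
    Plv, Vlv = result["Plv"], result["Vlv"]
    Qmt, Qav = result["Qmt"], result["Qav"]
    thr_mt, thr_av = _flow_threshold(Qmt), _flow_threshold(Qav)

    def corner_at(ti, flag="ok"):
        if ti is None:
            return Corner(P=math.nan, V=math.nan, t=math.nan, flag="not_detected")
        return Corner(P=_at(t, Plv, ti), V=_at(t, Vlv, ti), t=float(ti), flag=flag)

    mt_up = _upcrossings(t, Qmt, thr_mt)
    mt_down = _downcrossings(t, Qmt, thr_mt)
    av_up = _upcrossings(t, Qav, thr_av)
    t2 = av_up[0] if av_up else None
    av_down = [d for d in _downcrossings(t, Qav, thr_av) if t2 is None or d > t2]
    c1 = corner_at(mt_down[-1] if mt_down else None)
    c2 = corner_at(t2)
    c3 = corner_at(av_down[0] if av_down else None)
    c4 = corner_at(mt_up[0] if mt_up else None)

    if c1.flag == "ok" and c2.flag == "ok":
        if abs(c2.V - c1.V) > ISOVOLUMETRIC_TOL:
            c1.flag = c2.flag = "no_isovolumetric_contraction"
    if c3.flag == "ok" and c4.flag == "ok":
        if abs(c4.V - c3.V) > ISOVOLUMETRIC_TOL:
            c3.flag = c4.flag = "no_isovolumetric_relaxation"
    return [c1, c2, c3, c4]


@dataclass
class CycleMetrics:
    """Summary of one converged cardiac cycle (clinical units)."""

    SV: float                 # stroke volume, max − min of Vlv (ml)
    Vmin: float               # minimum LV volume (ml)
    Vmax: float               # maximum LV volume (ml)
    EDV: float                # end-diastolic volume (corner 1, else Vmax)
    ESV: float                # end-systolic volume (corner 3, else Vmin)
    corners: list             # four Corner records
    t_open: float             # mitral opening time (s)
    t_peakA: float            # time of peak aperture (or peak inflow) (s)
    t_close: float            # mitral closing time (s)
    open_duration: float      # t_close − t_open (s)
    Qmt_max: float            # peak transmitral flow (ml/s)
    Qmt_min: float            # minimum transmitral flow (ml/s; < 0 = backflow)
    regurgitant_volume: float  # |∫ min(Qmt, 0) dt| (ml)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["corners"] = [asdict(c) for c in self.corners]
        return d


def cycle_metrics(result: SimulationResult) -> CycleMetrics:
    """Extract all per-cycle summary metrics from one dense cycle.

    Stroke volume is max − min of the LV volume over the cycle — the
    only definition that applies when the isovolumetric phases have
    disappeared.  For a baseline-variant run (no aperture trace) the
    mitral open/close times come from the transmitral flow gate and
    the peak time from peak inflow.
    """
    t = result.t
    Vlv = result["Vlv"]
    Qmt = result["Qmt"]
    Vmin, Vmax = float(np.min(Vlv)), float(np.max(Vlv))
    corners = pv_corners(result)
    EDV = corners[0].V if corners[0].flag != "not_detected" else Vmax
    ESV = corners[2].V if corners[2].flag != "not_detected" else Vmin
    if "A" in result.data.columns:
        tim = valve_timing(result)
    else:
        thr = _flow_threshold(Qmt)
        ups = _upcrossings(t, Qmt, thr)
        downs = _downcrossings(t, Qmt, thr)
        if ups:
            tim = MitralTiming(opened=True, t_open=ups[0],
                               t_peak=float(t[int(np.argmax(Qmt))]),
                               t_close=downs[-1] if downs else float(t[-1]))
        else:
            tim = MitralTiming(opened=False)
    neg = np.minimum(Qmt, 0.0)
    regurg = float(abs(np.trapezoid(neg, t)))
    return CycleMetrics(
        SV=Vmax - Vmin, Vmin=Vmin, Vmax=Vmax, EDV=float(EDV), ESV=float(ESV),
        corners=corners,
        t_open=tim.t_open, t_peakA=tim.t_peak, t_close=tim.t_close,
        open_duration=tim.open_duration,
        Qmt_max=float(np.max(Qmt)), Qmt_min=float(np.min(Qmt)),
        regurgitant_volume=regurg,
    )


def compare_variants(baseline: SimulationResult,
                     extended: SimulationResult) -> list:
    """Corner-wise (ΔP, ΔV) = baseline − extended, four pairs.

    Both runs must use the same preset; differences quantify how far
    the dynamic-aperture model departs from the validated Heaviside
    formulation.
    """
    pb = baseline.meta.get("preset")
    pe = extended.meta.get("preset")
    if pb != pe:
        raise ValueError(f"preset mismatch: {pb!r} vs {pe!r}")
    cb = pv_corners(baseline)
    ce = pv_corners(extended)
    return [(b.P - e.P, b.V - e.V) for b, e in zip(cb, ce)]
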