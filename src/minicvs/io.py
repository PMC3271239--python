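"""Trajectory/metrics readers and writers, and synthetic analysis fixtures.

Trajectories are written as plain CSV (one header row, full double
precision — 17 significant digits — so regression comparisons are
exact) with a JSON sidecar carrying the run metadata.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .simulator import SimulationResult

__all__ = [
    "write_trajectory",
    "read_trajectory",
    "write_metrics",
    "generate_fixture",
    "FIXTURE_KINDS",
]

FIXTURE_KINDS = ("triangular_area", "rectangular_pv", "constant")


def _meta_path(csv_path) -> Path:
    p = Path(csv_path)
    return p.with_suffix(p.suffix + ".meta.json")


def write_trajectory(result: SimulationResult, csv_path,
                     meta_path=None) -> None:
    """Write the dense trajectory as CSV plus a JSON metadata sidecar."""
    csv_path = Path(csv_path)
    result.data.to_csv(csv_path, index=False, float_format="%.17g")
    mp = _meta_path(csv_path) if meta_path is None else Path(meta_path)
    mp.write_text(json.dumps(result.meta, indent=1, default=float))


def read_trajectory(csv_path, meta_path=None) -> SimulationResult:
    """Read a trajectory CSV (and its sidecar, if present) back."""
    csv_path = Path(csv_path)
    data = pd.read_csv(csv_path, float_precision="round_trip")
    mp = _meta_path(csv_path) if meta_path is None else Path(meta_path)
    meta = json.loads(mp.read_text()) if mp.exists() else {}
    return SimulationResult(data=data, meta=meta)


def write_metrics(metrics, path) -> None:
    """Write a CycleMetrics (or plain dict) as JSON."""
    d = metrics.to_dict() if hasattr(metrics, "to_dict") else dict(metrics)
    Path(path).write_text(json.dumps(d, indent=1, default=float))


def _empty_frame(t):
    n = t.size
    z = np.zeros(n)
    cols = {"t": t}
    for nm in ("Vpu", "Vlv", "Vao", "Vvc", "Vrv", "Vpa",
               "Qmt", "Qav", "Qtc", "Qpv",
               "Plv", "Prv", "Ppu", "Ppa", "Pao", "Pvc", "Pperi", "Vspt",
               "e", "Qsys", "Qpul", "Rmt", "Lmt"):
        cols[nm] = z.copy()
    return cols


def generate_fixture(kind: str, **params) -> SimulationResult:
    """Deterministic synthetic traces with analytically known metrics.

    ``triangular_area``: aperture rises linearly from ``t_open`` to a
    peak at ``t_peak`` and back to zero at ``t_close`` (transmitral
    flow proportional to the aperture), so valve timing is known
    exactly.

    ``rectangular_pv``: an idealised rectangular PV loop traversing
    (P_low, V_low) → (P_low, V_high) → (P_high, V_high) →
    (P_high, V_low), with valve flows consistent with the volume
    derivative, so the four corners are known exactly.

    ``constant``: a flat trajectory — every metric is zero.
    """
    D1 = float(params.pop("D1", 1.0))
    dt = float(params.pop("dt", 1e-3))
    t = np.arange(0.0, D1 + dt / 2, dt)
    meta = {"variant": "synthetic", "preset": f"fixture:{kind}", "D1": D1,
            "mitral": {"dc": 0.0, "eps": 0.0, "Amax": 1.0}}

    if kind == "triangular_area":
        t_open = float(params.pop("t_open", 0.3))
        t_peak = float(params.pop("t_peak", 0.5))
        t_close = float(params.pop("t_close", 0.8))
        Amax = float(params.pop("Amax", 1.0))
        if not t_open < t_peak < t_close <= D1:
            raise ValueError("need t_open < t_peak < t_close <= D1")
        cols = _empty_frame(t)
        A = np.interp(t, [0.0, t_open, t_peak, t_close, D1],
                      [0.0, 0.0, Amax, 0.0, 0.0])
        cols["A"] = A
        cols["Adot"] = np.gradient(A, t)
        cols["Qmt"] = 500.0 * A
        cols["Vlv"] = 50.0 + np.cumsum(cols["Qmt"]) * dt
        cols["Plv"] = np.full(t.size, 10.0)
        meta["mitral"]["Amax"] = Amax

    elif kind == "rectangular_pv":
        V_low = float(params.pop("V_low", 50.0))
        V_high = float(params.pop("V_high", 130.0))
        P_low = float(params.pop("P_low", 10.0))
        P_high = float(params.pop("P_high", 120.0))
        q = D1 / 4.0
        # filling | isovolumetric contraction | ejection | relaxation
        cols = _empty_frame(t)
        cols["Vlv"] = np.interp(t, [0.0, q, 2 * q, 3 * q, D1],
                                [V_low, V_high, V_high, V_low, V_low])
        cols["Plv"] = np.interp(t, [0.0, q, 2 * q, 3 * q, D1],
                                [P_low, P_low, P_high, P_high, P_low])
        rate = (V_high - V_low) / q
        cols["Qmt"] = np.where((t > 0) & (t < q), rate, 0.0)
        cols["Qav"] = np.where((t >= 2 * q) & (t < 3 * q), rate, 0.0)

    elif kind == "constant":
        cols = _empty_frame(t)
        cols["Vlv"] = np.full(t.size, float(params.pop("Vlv", 100.0)))
        cols["A"] = np.zeros(t.size)
        cols["Adot"] = np.zeros(t.size)

    else:
        raise ValueError(
            f"unknown fixture kind {kind!r}; valid kinds: {', '.join(FIXTURE_KINDS)}")
    if params:
        raise TypeError(f"unused fixture parameters: {sorted(params)}")
    return SimulationResult(data=pd.DataFrame(cols), meta=meta)
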