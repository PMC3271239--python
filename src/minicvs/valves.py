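"""Heaviside valve law: "open on pressure, close on flow".

A diode valve opens as soon as the upstream pressure exceeds the
downstream pressure and stays open while flow remains positive; flow
through a closed valve is suppressed.  The composite gate is

    gate = H(H(Pup − Pdown) + H(Q) − 0.5)

with H the Heaviside step, H(0) = 0 exactly.  Flow through an open
valve carries inertia:  L·dQ/dt = (Pup − Pdown) − Q·R.

Volume balances use the clipped flow H(Q)·Q so that a (numerically)
negative valve flow never moves volume backwards.
"""

from __future__ import annotations

import math

from .parameters import ValveParams

__all__ = [
    "heaviside",
    "smooth_heaviside",
    "valve_gate",
    "valve_flow_rhs",
    "chamber_volume_rhs",
    "algebraic_flow",
]


def heaviside(x: float) -> float:
    """Heaviside step with H(0) = 0."""
    return 1.0 if x > 0.0 else 0.0


def smooth_heaviside(x: float, k: float = 500.0) -> float:
    """Logistic surrogate 1/(1 + exp(−k·x)); note it gives 0.5 at x = 0,
    unlike the exact gate."""
    if k * x < -500.0:
        return 0.0
    if k * x > 500.0:
        return 1.0
    return 1.0 / (1.0 + math.exp(-k * x))


def valve_gate(Pup: float, Pdown: float, Q: float,
               mode: str = "discrete", k: float = 500.0) -> float:
    """Composite valve gate: 1 iff (Pup > Pdown) or (Q > 0)."""
    if mode == "smooth":
        H = lambda x: smooth_heaviside(x, k)
    else:
        H = heaviside
    return H(H(Pup - Pdown) + H(Q) - 0.5)


def valve_flow_rhs(Pup: float, Pdown: float, Q: float, v: ValveParams,
                   mode: str = "discrete", k: float = 500.0) -> float:
    """dQ/dt = gate·((Pup − Pdown) − Q·R)/L (ml/s²)."""
    gate = valve_gate(Pup, Pdown, Q, mode=mode, k=k)
    if gate == 0.0:
        return 0.0
    return gate * ((Pup - Pdown) - Q * v.R) / v.L


def chamber_volume_rhs(Qin: float, Qout: float) -> float:
    """dV/dt = H(Qin)·Qin − H(Qout)·Qout (ml/s)."""
    return heaviside(Qin) * Qin - heaviside(Qout) * Qout


def algebraic_flow(Pfrom: float, Pto: float, R: float) -> float:
    """Ohmic segment flow (Pfrom − Pto)/R; may be negative — the caller
    Heaviside-clips it where the model requires one-way flow."""
    return (Pfrom - Pto) / R
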