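"""Cardiac driver (activation) function.

The driver e(t) is a periodic sum of Gaussians interpolating each
active chamber between its end-diastolic (e = 0) and end-systolic
(e = 1) pressure-volume relationships:

    e(t) = sum_i A_i · exp(−B_i·((t mod D1) − C_i)²),   D1 = 60/HR.

The Gaussian is evaluated on the folded time (t mod D1) without
wrap-around image terms, so with the default single Gaussian
(A1 = 1, B1 = 80 s⁻², C1 = 0.27 s) e(t) has period D1 exactly and a
small residual discontinuity at the period boundary
(exp(−80·0.27²) ≈ 3e−3), by construction.
"""

from __future__ import annotations

import math

from .parameters import DriverParams

__all__ = ["driver"]


def driver(t: float, p: DriverParams) -> float:
    """Activation e(t) in (0, sum(A)] at time ``t`` (s)."""
    tau = math.fmod(t, p.D1)
    if tau < 0:
        tau += p.D1
    return sum(a * math.exp(-b * (tau - c) ** 2)
               for a, b, c in zip(p.A, p.B, p.C))
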