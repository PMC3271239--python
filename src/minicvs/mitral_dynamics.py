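"""Dynamic mitral valve: area-dependent impedance and aperture oscillator.

Instead of a diode, the mitral valve is described by its effective
aperture area A(t) (cm²).  The transmitral flow obeys

    dQmt/dt = (Ppu − Plv)/Lmt(A) − Qmt·Rmt(A)/Lmt(A) + Qmt·Ȧ/A,

with no Heaviside gate: closure is expressed through the impedance,
which grows without bound as A → 0 (regularised by A + eps).

The aperture itself is a damped oscillator forced by the
atrioventricular pressure difference acting on the still-covered
area (Amax − A):

    Ä/ω² + 2·D·Ȧ/ω + A = (Amax − A)·Ks·(Ppu − Plv)

gated by H(H(Ppu − Plv) + H(A − dc) − 0.5) so the aperture freezes at
its floor (0 healthy; the closure defect dc under ischemic mitral
insufficiency) whenever the gradient is adverse.

Two impedance laws are available.  The cylindrical-duct (Poiseuille /
blood-column) formulas

    Rmt = 8·pi·mu·l / A²,     Lmt = rho·l / A

are evaluated in SI and converted to clinical units.  With
physiological rho and mu, however, their ratio Lmt/Rmt = rho·A/(8·pi·mu)
is independent of l and of order 1 s at physiological areas — two
orders slower than the validated open-valve impedance ratio — so no
single column length can match both validated coefficients.  The
default "anchored" law therefore keeps only the area scaling
(R ∝ A⁻², L ∝ A⁻¹), anchored at the validated open-valve R, L at the
reference area A_ref.
"""

from __future__ import annotations

import math

from .parameters import MitralDynamicsParams

__all__ = [
    "MMHG_S_PER_ML_IN_SI",
    "mitral_resistance",
    "mitral_inertance",
    "effective_resistance",
    "effective_inertance",
    "mitral_flow_rhs",
    "aperture_gate",
    "aperture_rhs",
    "aperture_equilibrium",
]

#: 1 mmHg·s/ml in Pa·s/m³ (and 1 mmHg·s²/ml in Pa·s²/m³)
MMHG_S_PER_ML_IN_SI = 1.33322e8

_CM2_TO_M2 = 1.0e-4


def mitral_resistance(A: float, p: MitralDynamicsParams) -> float:
    """Cylindrical-duct viscous resistance 8·pi·mu·l/(A + eps)², in mmHg·s/ml.

    Evaluated in SI (A in cm² converted to m²) and divided by
    1.33322e8 Pa·s/m³ per mmHg·s/ml.  Monotone decreasing in A and
    finite at A = 0 thanks to the eps regularisation.
    """
    A_si = (A + p.eps) * _CM2_TO_M2
    R_si = 8.0 * math.pi * p.mu * p.l / (A_si * A_si)
    return R_si / MMHG_S_PER_ML_IN_SI


def mitral_inertance(A: float, p: MitralDynamicsParams) -> float:
    """Blood-column inertance rho·l/(A + eps), converted to mmHg·s²/ml."""
    A_si = (A + p.eps) * _CM2_TO_M2
    return p.rho * p.l / A_si / MMHG_S_PER_ML_IN_SI


def effective_resistance(A: float, p: MitralDynamicsParams) -> float:
    """Area-dependent resistance under the configured law (mmHg·s/ml).

    A is floored at 0 so that a (smoothed-gate) aperture transiently
    below its floor cannot defeat the eps regularisation.
    """
    A = A if A > 0.0 else 0.0
    if p.law == "cylindrical":
        return mitral_resistance(A, p)
    r = p.A_ref / (A + p.eps)
    return p.R_open * r * r


def effective_inertance(A: float, p: MitralDynamicsParams) -> float:
    """Area-dependent inertance under the configured law (mmHg·s²/ml)."""
    A = A if A > 0.0 else 0.0
    if p.law == "cylindrical":
        return mitral_inertance(A, p)
    return p.L_open * p.A_ref / (A + p.eps)


def mitral_flow_rhs(Ppu: float, Plv: float, Qmt: float, A: float,
                    Adot: float, p: MitralDynamicsParams) -> float:
    """Ungated transmitral flow derivative dQmt/dt (ml/s²).

    (Ppu − Plv)/Lmt − Qmt·Rmt/Lmt + Qmt·Ȧ/(A + eps); the convective
    term accounts for the moving aperture boundary.
    """
    L = effective_inertance(A, p)
    R = effective_resistance(A, p)
    Apos = A if A > 0.0 else 0.0
    return (Ppu - Plv) / L - Qmt * R / L + Qmt * Adot / (Apos + p.eps)


def aperture_gate(Ppu: float, Plv: float, A: float, p: MitralDynamicsParams) -> float:
    """H(H(Ppu − Plv) + H(A − dc) − 0.5): the aperture moves iff the
    gradient is favourable or the valve is off its floor."""
    open_on_pressure = 1.0 if (Ppu - Plv) > 0.0 else 0.0
    off_floor = 1.0 if (A - p.dc) > 0.0 else 0.0
    return 1.0 if (open_on_pressure + off_floor - 0.5) > 0.0 else 0.0


def aperture_rhs(Ppu: float, Plv: float, A: float, Adot: float,
                 p: MitralDynamicsParams) -> tuple:
    """(dA/dt, dȦ/dt) of the gated forced oscillator (cm²/s, cm²/s²).

    dȦ/dt = ω²·(Amax − A)·Ks·(Ppu − Plv) − 2·D·Ȧ − ω²·A, gated.

    With dc = 0 this is the healthy-valve form; dc > 0 freezes the
    aperture at the closure defect instead of at zero.
    """
    gate = aperture_gate(Ppu, Plv, A, p)
    if gate == 0.0:
        return 0.0, 0.0
    w = p.omega
    dAdot = (w * w * (p.Amax - A) * p.Ks * (Ppu - Plv)
             - 2.0 * p.D * Adot - w * w * A)
    return Adot, dAdot


def aperture_equilibrium(dP: float, p: MitralDynamicsParams) -> float:
    """Steady aperture under a clamped favourable gradient dP (mmHg):

    A* = Amax·Ks·dP / (1 + Ks·dP)  — always below Amax.
    """
    x = p.Ks * dP
    return p.Amax * x / (1.0 + x)
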