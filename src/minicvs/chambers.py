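"""Chamber pressure-volume relations and the ventricular-interaction solve.

Active chambers (ventricular free walls, septum) blend a linear
end-systolic PV relationship with an exponential end-diastolic one,
weighted by the activation e(t):

    P(V, e) = e·Ees·(V − Vd) + (1 − e)·P0·(exp(lam·(V − V0)) − 1)

Passive chambers (great vessels) are linear, P = E·V, with the
intrathoracic ones offset by the thoracic cavity pressure.

Ventricular interaction couples the two ventricles through the septum:
a volume Vspt is displaced so that the septal free-wall pressure
balances the trans-septal pressure difference, and a pericardial
pressure acting on the combined ventricular volume is added to both.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.optimize import brentq

from .parameters import ActiveChamberParams, ModelParameters, PassiveChamberParams

__all__ = [
    "espvr",
    "edpvr",
    "active_pressure",
    "passive_pressure",
    "pericardial_pressure",
    "VentricularInteractionResult",
    "solve_ventricular_interaction",
]

_EXP_MAX = 700.0  # exp argument beyond which edpvr refuses to evaluate


def espvr(V: float, p: ActiveChamberParams) -> float:
    """End-systolic pressure Ees·(V − Vd) in mmHg."""
    return p.Ees * (V - p.Vd)


def edpvr(V: float, p: ActiveChamberParams) -> float:
    """End-diastolic pressure P0·(exp(lam·(V − V0)) − 1) in mmHg.

    Raises OverflowError for volumes that would overflow the
    exponential rather than silently returning infinity.
    """
    x = p.lam * (V - p.V0)
    if x > _EXP_MAX:
        raise OverflowError(
            f"edpvr exponent lam*(V - V0) = {x:.3g} too large (V = {V:.6g} ml)"
        )
    return p.P0 * (math.exp(x) - 1.0)


def _edpvr_slope(V: float, p: ActiveChamberParams) -> float:
    return p.P0 * p.lam * math.exp(p.lam * (V - p.V0))


def active_pressure(V: float, e: float, p: ActiveChamberParams) -> float:
    """Activation-weighted chamber pressure e·ESPVR + (1 − e)·EDPVR."""
    return e * espvr(V, p) + (1.0 - e) * edpvr(V, p)


def _active_slope(V: float, e: float, p: ActiveChamberParams) -> float:
    return e * p.Ees + (1.0 - e) * _edpvr_slope(V, p)


def passive_pressure(V: float, p: PassiveChamberParams, Pth: float = 0.0) -> float:
    """Linear chamber pressure E·V, offset by Pth when intrathoracic."""
    P = p.E * V
    if p.thoracic:
        P += Pth
    return P


def pericardial_pressure(Vlv: float, Vrv: float, params: ModelParameters) -> float:
    """Pericardial pressure on the combined ventricular volume, plus Pth."""
    if not params.numerics.interaction:
        return params.circ.Pth
    return edpvr(Vlv + Vrv, params.pcd) + params.circ.Pth


@dataclass
class VentricularInteractionResult:
    Vspt: float   # septal volume displacement (ml)
    Plv: float    # left ventricular pressure (mmHg)
    Prv: float    # right ventricular pressure (mmHg)
    Pperi: float  # pericardial pressure (mmHg)


class SeptumSolveError(RuntimeError):
    pass


_BRACKET = 50.0       # ml, half-width of the brentq fallback bracket
_RES_TOL = 1.0e-10    # mmHg, residual tolerance on the septum balance


def _septum_residual(Vspt, Vlv, Vrv, e, params):
    return (active_pressure(Vspt, e, params.spt)
            - active_pressure(Vlv - Vspt, e, params.lvf)
            + active_pressure(Vrv + Vspt, e, params.rvf))


def solve_septum(Vlv: float, Vrv: float, e: float, params: ModelParameters,
                 x0: float | None = None) -> float:
    """Septal displacement Vspt balancing Pspt = Plvf − Prvf.

    The residual is strictly increasing in Vspt, so the root is unique.
    Newton iteration from ``x0`` (warm start) with an analytic slope,
    falling back to bracketed brentq on [Vd − 50, Vd + 50] ml.
    """
    x = params.spt.Vd if x0 is None else x0
    for _ in range(30):
        f = _septum_residual(x, Vlv, Vrv, e, params)
        if abs(f) < _RES_TOL:
            return x
        df = (_active_slope(x, e, params.spt)
              + _active_slope(Vlv - x, e, params.lvf)
              + _active_slope(Vrv + x, e, params.rvf))
        step = f / df
        x -= step
        if abs(step) < 1e-14:
            return x
    lo, hi = params.spt.Vd - _BRACKET, params.spt.Vd + _BRACKET
    try:
        return brentq(_septum_residual, lo, hi,
                      args=(Vlv, Vrv, e, params), xtol=1e-12, rtol=1e-15)
    except ValueError as exc:
        raise SeptumSolveError(
            f"septum solve failed at Vlv={Vlv:.6g} ml, Vrv={Vrv:.6g} ml, "
            f"e={e:.6g}: {exc}"
        ) from exc


def solve_ventricular_interaction(
    Vlv: float, Vrv: float, e: float, params: ModelParameters,
    x0: float | None = None,
) -> VentricularInteractionResult:
    """Ventricular pressures with septal displacement and pericardium.

    With interaction disabled (numerics.interaction = False) the septum
    is frozen at its zero-pressure volume and the pericardial pressure
    reduces to the thoracic offset, so each ventricle decouples to its
    free-wall relation.
    """
    if params.numerics.interaction:
        Vspt = solve_septum(Vlv, Vrv, e, params, x0=x0)
    else:
        Vspt = params.spt.Vd
    Pperi = pericardial_pressure(Vlv, Vrv, params)
    Plv = active_pressure(Vlv - Vspt, e, params.lvf) + Pperi
    Prv = active_pressure(Vrv + Vspt, e, params.rvf) + Pperi
    return VentricularInteractionResult(Vspt=Vspt, Plv=Plv, Prv=Prv, Pperi=Pperi)
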