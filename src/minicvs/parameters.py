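"""Typed parameter containers, presets and plain-text config I/O.

Unit conventions
----------------
The internal unit system is clinical throughout: pressures in mmHg,
volumes in ml, times in s, flows in ml/s, resistances in mmHg·s/ml,
inertances in mmHg·s²/ml, elastances in mmHg/ml.  Mitral aperture areas
are stored in cm².  The cylindrical-duct hydraulic laws are evaluated in
SI and converted (1 mmHg·s/ml = 1.33322e8 Pa·s/m³); see
:mod:`minicvs.mitral_dynamics`.

Two presets are built in:

``healthy``
    the validated baseline heart with an intact mitral valve,
``imi``
    the post-infarct remodelled heart with ischemic mitral
    insufficiency: left-ventricular end-systolic elastance halved,
    dead volumes raised, a dilated mitral annulus (larger maximal
    aperture) and a permanent closure defect ``dc``.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Union

__all__ = [
    "ActiveChamberParams",
    "PassiveChamberParams",
    "ValveParams",
    "MitralDynamicsParams",
    "DriverParams",
    "CirculationParams",
    "InitialVolumes",
    "NumericsParams",
    "ModelParameters",
    "preset",
    "load_config",
    "loads_config",
    "dumps_config",
    "save_config",
    "PRESET_NAMES",
    "VARIANTS",
]

VARIANTS = ("heaviside", "dynamic_mv")
PRESET_NAMES = ("healthy", "imi")


class ConfigError(ValueError):
    """Raised when a config file cannot be parsed or violates an invariant."""


def _require(cond: bool, name: str, msg: str) -> None:
    if not cond:
        raise ConfigError(f"invalid parameter '{name}': {msg}")


@dataclass
class ActiveChamberParams:
    """End-systolic / end-diastolic PV-relationship parameters.

    Ees: end-systolic elastance (mmHg/ml); Vd: zero-pressure volume of
    the ESPVR (ml); V0: zero-pressure volume of the EDPVR (ml);
    lam: EDPVR exponent (1/ml); P0: EDPVR scale (mmHg).
    """

    Ees: float
    Vd: float
    V0: float
    lam: float
    P0: float

    def validate(self, name: str = "chamber") -> None:
        _require(self.Ees >= 0, f"{name}.Ees", "must be >= 0")
        _require(self.lam > 0, f"{name}.lam", "must be > 0")
        _require(self.P0 >= 0, f"{name}.P0", "must be >= 0")
        _require(self.Vd >= 0, f"{name}.Vd", "must be >= 0")
        _require(self.V0 >= 0, f"{name}.V0", "must be >= 0")


@dataclass
class PassiveChamberParams:
    """Constant-elastance chamber: P = E·V (+ thoracic offset if flagged).

    ``thoracic`` marks chambers inside the thoracic cavity, whose
    pressure carries the (negative) intrathoracic pressure offset.
    """

    E: float
    thoracic: bool = False

    def validate(self, name: str = "chamber") -> None:
        _require(self.E >= 0, f"{name}.E", "must be >= 0")


@dataclass
class ValveParams:
    """Fixed viscous resistance R (mmHg·s/ml) and inertance L (mmHg·s²/ml)."""

    R: float
    L: float

    def validate(self, name: str = "valve") -> None:
        _require(self.R > 0, f"{name}.R", "must be > 0")
        _require(self.L > 0, f"{name}.L", "must be > 0")


@dataclass
class MitralDynamicsParams:
    """Parameters of the forced-oscillator mitral aperture model.

    The aperture area A (cm²) obeys an underdamped oscillator driven
    by the atrioventricular pressure gradient; Ks (1/mmHg) makes the
    forcing Ks·ΔP dimensionless, Amax (cm²) is the maximal aperture,
    omega (rad/s) the natural frequency, D (1/s) the damping rate
    (damping ratio D/omega) and dc (cm²) the permanent closure defect
    (0 for a healthy valve).  The presets carry the static gain as
    applied to the gradient expressed in SI units, i.e. 0.05 per mmHg
    × 133.322 Pa/mmHg = 6.6661: with the nominal 0.05 the equilibrium
    opening Amax·Ks·ΔP/(1 + Ks·ΔP) stays below a quarter of Amax under
    physiological gradients and the valve never opens effectively.

    rho, mu, l are blood density (kg/m³), viscosity (N·s/m²) and the
    blood-column length through the valve (m), used by the literal
    cylindrical-duct R/L laws; eps (cm²) regularises divisions by A.

    ``law`` selects how the area-dependent valve impedance is built:
    ``anchored`` (default) scales the validated open-valve R, L
    (``R_open``, ``L_open``, taken at ``A_ref``) by (A_ref/A)² and
    (A_ref/A); ``cylindrical`` evaluates the Poiseuille/column formulas
    from rho, mu, l directly.
    """

    Ks: float = 6.6661
    Amax: float = 1.1
    omega: float = 30.0
    D: float = 10.0
    dc: float = 0.0
    rho: float = 1050.0
    mu: float = 4.0e-3
    l: float = 0.02
    eps: float = 1.0e-4
    law: str = "anchored"
    R_open: float = 0.0158
    L_open: float = 7.6968e-5
    A_ref: float = 1.1

    def validate(self, name: str = "mitral") -> None:
        _require(self.Ks > 0, f"{name}.Ks", "must be > 0")
        _require(self.Amax > 0, f"{name}.Amax", "must be > 0")
        _require(self.omega > 0, f"{name}.omega", "must be > 0")
        _require(self.D > 0, f"{name}.D", "must be > 0")
        _require(0 <= self.dc < self.Amax, f"{name}.dc", "must satisfy 0 <= dc < Amax")
        _require(self.eps > 0, f"{name}.eps", "must be > 0")
        _require(self.rho > 0, f"{name}.rho", "must be > 0")
        _require(self.mu > 0, f"{name}.mu", "must be > 0")
        _require(self.l > 0, f"{name}.l", "must be > 0")
        _require(self.law in ("anchored", "cylindrical"), f"{name}.law",
                 "must be 'anchored' or 'cylindrical'")
        _require(self.R_open > 0, f"{name}.R_open", "must be > 0")
        _require(self.L_open > 0, f"{name}.L_open", "must be > 0")
        _require(self.A_ref > 0, f"{name}.A_ref", "must be > 0")


@dataclass
class DriverParams:
    """Cardiac activation (driver) function parameters.

    e(t) = sum_i A_i·exp(−B_i·((t mod D1) − C_i)²), with D1 = 60/HR.
    A are dimensionless magnitudes in [0, 1], B widths (s⁻²), C delays
    (s), HR the heart rate (beats/min).
    """

    A: tuple = (1.0,)
    B: tuple = (80.0,)
    C: tuple = (0.27,)
    HR: float = 60.0

    @property
    def N(self) -> int:
        return len(self.A)

    @property
    def D1(self) -> float:
        """Cardiac cycle period (s), D1 = 60/HR."""
        return 60.0 / self.HR

    def validate(self, name: str = "driver") -> None:
        _require(self.N >= 1, f"{name}.A", "needs at least one Gaussian")
        _require(len(self.B) == self.N and len(self.C) == self.N,
                 f"{name}.B/C", "must match length of A")
        _require(self.HR > 0, f"{name}.HR", "must be > 0")
        for i, (a, b, c) in enumerate(zip(self.A, self.B, self.C)):
            _require(0 <= a <= 1, f"{name}.A[{i}]", "must be in [0, 1]")
            _require(b > 0, f"{name}.B[{i}]", "must be > 0")
            _require(0 <= c < self.D1, f"{name}.C[{i}]", "must be in [0, D1)")


@dataclass
class CirculationParams:
    """Systemic/pulmonary resistances, total blood volume, thoracic pressure.

    Rsys, Rpul in mmHg·s/ml; Vtot in litres; Pth in mmHg (negative:
    intrathoracic pressure).  Rsys and Rpul are not part of the printed
    parameter set; the defaults are calibrated so the healthy preset
    reproduces its reference stroke volume (79.43 ml) and minimum LV
    volume (47.47 ml).
    """

    Rsys: float = 1.2021
    Rpul: float = 0.065
    Vtot: float = 5.5
    Pth: float = -4.0

    def validate(self, name: str = "circ") -> None:
        _require(self.Rsys > 0, f"{name}.Rsys", "must be > 0")
        _require(self.Rpul > 0, f"{name}.Rpul", "must be > 0")
        _require(self.Vtot > 0, f"{name}.Vtot", "must be > 0")


@dataclass
class InitialVolumes:
    """Initial stressed chamber volumes (ml) used to start the integration.

    The periodic steady state is insensitive to the split as long as
    the total stressed volume (defaults: 1672 ml) is preserved; the
    default distribution is the healthy preset's own converged
    cycle-start state, so runs reach their periodic orbit quickly.
    """

    Vpu: float = 1038.83
    Vlv: float = 126.85
    Vao: float = 115.83
    Vvc: float = 252.72
    Vrv: float = 116.32
    Vpa: float = 21.42

    def total(self) -> float:
        return self.Vpu + self.Vlv + self.Vao + self.Vvc + self.Vrv + self.Vpa

    def validate(self, name: str = "init") -> None:
        for f in fields(self):
            _require(getattr(self, f.name) >= 0, f"{name}.{f.name}", "must be >= 0")


@dataclass
class NumericsParams:
    """Solver and model-structure switches.

    gate_mode: 'discrete' uses the exact Heaviside gates (H(0) = 0);
    'smooth' replaces H by a logistic of steepness k_smooth (for solvers
    or studies that need a differentiable right-hand side).
    interaction: disable to freeze the septum at its zero-pressure
    volume and reduce the pericardial pressure to the thoracic offset.
    """

    gate_mode: str = "discrete"
    k_smooth: float = 500.0
    interaction: bool = True
    rtol: float = 1.0e-7
    atol: float = 1.0e-8
    max_step: float = 2.0e-3
    dt_out: float = 1.0e-3
    ss_tol: float = 5.0e-4
    max_cycles: int = 60

    def validate(self, name: str = "numerics") -> None:
        _require(self.gate_mode in ("discrete", "smooth"), f"{name}.gate_mode",
                 "must be 'discrete' or 'smooth'")
        _require(self.k_smooth > 0, f"{name}.k_smooth", "must be > 0")
        _require(self.rtol > 0 and self.atol > 0, f"{name}.rtol/atol", "must be > 0")
        _require(self.max_step > 0, f"{name}.max_step", "must be > 0")
        _require(self.dt_out > 0, f"{name}.dt_out", "must be > 0")
        _require(self.ss_tol > 0, f"{name}.ss_tol", "must be > 0")
        _require(self.max_cycles >= 1, f"{name}.max_cycles", "must be >= 1")


@dataclass
class ModelParameters:
    """Full parameter bundle for one simulation."""

    lvf: ActiveChamberParams
    rvf: ActiveChamberParams
    spt: ActiveChamberParams
    pcd: ActiveChamberParams
    vc: PassiveChamberParams
    pa: PassiveChamberParams
    pu: PassiveChamberParams
    ao: PassiveChamberParams
    valves: dict = field(default_factory=dict)
    mitral: MitralDynamicsParams = field(default_factory=MitralDynamicsParams)
    driver: DriverParams = field(default_factory=DriverParams)
    circ: CirculationParams = field(default_factory=CirculationParams)
    init: InitialVolumes = field(default_factory=InitialVolumes)
    numerics: NumericsParams = field(default_factory=NumericsParams)
    variant: str = "dynamic_mv"
    preset_name: str = "custom"

    def validate(self) -> "ModelParameters":
        for nm in ("lvf", "rvf", "spt", "pcd"):
            getattr(self, nm).validate(nm)
        for nm in ("vc", "pa", "pu", "ao"):
            getattr(self, nm).validate(nm)
        _require(set(self.valves) == {"mt", "tc", "av", "pv"}, "valves",
                 "must define exactly mt, tc, av, pv")
        for nm, v in self.valves.items():
            v.validate(f"valves.{nm}")
        self.mitral.validate("mitral")
        self.driver.validate("driver")
        self.circ.validate("circ")
        self.init.validate("init")
        self.numerics.validate("numerics")
        _require(self.variant in VARIANTS, "variant",
                 f"must be one of {VARIANTS}")
        return self


def _healthy() -> ModelParameters:
    return ModelParameters(
        lvf=ActiveChamberParams(Ees=2.8798, Vd=0.0, V0=0.0, lam=0.033, P0=0.1203),
        rvf=ActiveChamberParams(Ees=0.5850, Vd=0.0, V0=0.0, lam=0.023, P0=0.2157),
        spt=ActiveChamberParams(Ees=48.7540, Vd=2.00, V0=2.00, lam=0.435, P0=1.1101),
        # pericardium: EDPVR-only chamber on Vlv+Vrv (Ees, Vd unused)
        pcd=ActiveChamberParams(Ees=0.0, Vd=0.0, V0=200.00, lam=0.030, P0=0.5003),
        vc=PassiveChamberParams(E=0.0059, thoracic=False),
        pa=PassiveChamberParams(E=0.3690, thoracic=True),
        pu=PassiveChamberParams(E=0.0073, thoracic=True),
        # the baseline table truncates the aortic elastance to "0.0";
        # the validated source model's value is adopted and config-exposed
        ao=PassiveChamberParams(E=0.6913, thoracic=False),
        valves={
            "mt": ValveParams(R=0.0158, L=7.6968e-5),
            "tc": ValveParams(R=0.0237, L=8.0093e-5),
            "av": ValveParams(R=0.0180, L=1.2189e-4),
            "pv": ValveParams(R=0.0055, L=1.4868e-4),
        },
        # Ks: Table value 0.05 1/mmHg applied to the gradient in Pa
        mitral=MitralDynamicsParams(Ks=6.6661, Amax=1.1, omega=30.0, D=10.0, dc=0.0),
        driver=DriverParams(A=(1.0,), B=(80.0,), C=(0.27,), HR=60.0),
        circ=CirculationParams(),
        variant="dynamic_mv",
        preset_name="healthy",
    )


def preset(name: str) -> ModelParameters:
    """Return a validated built-in parameter set.

    ``healthy``: baseline heart, intact valve (dc = 0).
    ``imi``: remodelled heart with ischemic mitral insufficiency —
    lvf Ees halved to 1.4399 mmHg/ml, Vd = 30 ml, V0 = 20 ml,
    lam = 0.023 1/ml; Amax = 1.3 cm² (annular dilation); dc = 0.2 cm².
    """
    if name == "healthy":
        return _healthy().validate()
    if name == "imi":
        p = _healthy()
        p.lvf = ActiveChamberParams(Ees=1.4399, Vd=30.0, V0=20.0, lam=0.023, P0=0.1203)
        p.mitral = replace(p.mitral, Amax=1.3, dc=0.2)
        # remodelled heart's own converged cycle-start distribution
        # (same total stressed volume as the healthy preset)
        p.init = InitialVolumes(Vpu=1032.53, Vlv=181.53, Vao=85.74,
                                Vvc=262.03, Vrv=89.04, Vpa=21.09)
        p.preset_name = "imi"
        return p.validate()
    raise ConfigError(
        f"unknown preset '{name}'; valid presets are: {', '.join(PRESET_NAMES)}"
    )


# ---------------------------------------------------------------------------
# Flat key = value config dialect
# ---------------------------------------------------------------------------

_TUPLE_FIELDS = {"A", "B", "C"}


def _to_text(value) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, tuple):
        return ", ".join(repr(float(v)) for v in value)
    if isinstance(value, float):
        return repr(value)
    return str(value)


def _flatten(params: ModelParameters) -> dict:
    out: dict[str, str] = {}
    out["variant"] = params.variant
    out["preset"] = params.preset_name
    for group in ("lvf", "rvf", "spt", "pcd", "vc", "pa", "pu", "ao",
                  "mitral", "driver", "circ", "init", "numerics"):
        obj = getattr(params, group)
        for f in fields(obj):
            out[f"{group}.{f.name}"] = _to_text(getattr(obj, f.name))
    for vname, v in params.valves.items():
        out[f"valves.{vname}.R"] = _to_text(v.R)
        out[f"valves.{vname}.L"] = _to_text(v.L)
    return out


def dumps_config(params: ModelParameters) -> str:
    """Serialise to the flat ``key = value`` text dialect (round-trips exactly)."""
    lines = ["# minicvs configuration (flat key = value; '#' starts a comment)"]
    lines += [f"{k} = {v}" for k, v in sorted(_flatten(params).items())]
    return "\n".join(lines) + "\n"


def save_config(params: ModelParameters, path) -> None:
    Path(path).write_text(dumps_config(params))


def _parse_value(field_obj, raw: str, key: str):
    t = field_obj.type
    raw = raw.strip()
    if t in ("bool", bool):
        if raw.lower() in ("true", "1", "yes"):
            return True
        if raw.lower() in ("false", "0", "no"):
            return False
        raise ConfigError(f"invalid parameter '{key}': expected boolean, got {raw!r}")
    if t in ("int", int):
        return int(raw)
    if t in ("str", str):
        return raw
    if t in ("tuple", tuple):
        return tuple(float(x) for x in raw.split(","))
    try:
        return float(raw)
    except ValueError as exc:
        raise ConfigError(f"invalid parameter '{key}': {exc}") from None


def loads_config(text: str, base: Union[ModelParameters, None] = None) -> ModelParameters:
    """Parse the flat config dialect; unspecified fields default to ``base``
    (the healthy preset if not given)."""
    params = base if base is not None else preset("healthy")
    params = dataclasses.replace(params)  # shallow copy; groups replaced below
    params.valves = dict(params.valves)
    pending: dict[str, dict] = {}
    valve_pending: dict[str, dict] = {}
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"line {lineno}: expected 'key = value', got {line!r}")
        key, raw = (s.strip() for s in line.split("=", 1))
        if key == "variant":
            params.variant = raw
            continue
        if key == "preset":
            params.preset_name = raw
            continue
        parts = key.split(".")
        if parts[0] == "valves":
            if len(parts) != 3 or parts[2] not in ("R", "L"):
                raise ConfigError(f"invalid parameter '{key}'")
            valve_pending.setdefault(parts[1], {})[parts[2]] = float(raw)
            continue
        if len(parts) != 2 or not hasattr(params, parts[0]):
            raise ConfigError(f"invalid parameter '{key}': unknown group")
        group, fname = parts
        obj = getattr(params, group)
        fmap = {f.name: f for f in fields(obj)}
        if fname not in fmap:
            raise ConfigError(f"invalid parameter '{key}': unknown field")
        pending.setdefault(group, {})[fname] = _parse_value(fmap[fname], raw, key)
    for group, kv in pending.items():
        setattr(params, group, replace(getattr(params, group), **kv))
    for vname, kv in valve_pending.items():
        if vname not in params.valves:
            raise ConfigError(f"invalid parameter 'valves.{vname}': unknown valve")
        params.valves[vname] = replace(params.valves[vname], **kv)
    return params.validate()


def load_config(path, base: Union[ModelParameters, None] = None) -> ModelParameters:
    """Load and validate a config file; missing fields fall back to the
    healthy preset (or ``base``)."""
    p = Path(path)
    if not p.exists():
        raise ConfigError(f"config file not found: {p}")
    return loads_config(p.read_text(), base=base)
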