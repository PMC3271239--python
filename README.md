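# minicvs

A closed-loop, lumped-parameter model of the human cardiovascular system
with a resolved mitral valve, for studying how valve dysfunction —
specifically ischemic mitral insufficiency (IMI), the incomplete closure
that follows post-infarct ventricular remodelling — reshapes global
hemodynamics: pressure–volume (PV) loops, transmitral flow, and the
timing of valve opening and closure.

It is aimed at computational physiologists and biomedical engineers who
want a minimal, fully inspectable six-chamber circulation in which the
mitral valve is not a diode but a dynamical system of its own.

## The model

Six elastic chambers in a closed loop: left ventricle (lv), aorta (ao),
vena cava (vc), right ventricle (rv), pulmonary artery (pa) and
pulmonary veins (pu). The ventricles are time-varying-elastance
chambers whose pressure blends the end-systolic and end-diastolic PV
relationships

    ESPVR: P_ES(V) = E_ES (V − V_d)
    EDPVR: P_ED(V) = P_0 (e^{λ(V − V_0)} − 1)
    P(V, t) = e(t) P_ES(V) + (1 − e(t)) P_ED(V)

under a periodic Gaussian activation (driver)
e(t) = Σ A_i exp(−B_i((t mod D_1) − C_i)²). Ventricular interaction is
carried by a septal volume displacement V_spt balancing the trans-septal
pressure, plus a pericardial EDPVR on the combined ventricular volume.
The great vessels are linear chambers P = E·V (pulmonary vessels offset
by the thoracic pressure P_th).

Valves obey the "open on pressure, close on flow" law: inertial flow
L dQ/dt = ΔP − QR gated by H(H(ΔP) + H(Q) − 0.5), with H(0) = 0. Two
model variants differ only at the mitral valve:

* **`heaviside`** — the validated baseline: the mitral valve is a
  gated diode like the other three.
* **`dynamic_mv`** — the mitral aperture area A(t) (cm²) is a forced,
  underdamped oscillator driven by the atrioventricular gradient,

      Ä/ω² + (2D/ω²) Ȧ + A = (A_max − A) · K_s (P_pu − P_lv),

  gated so A freezes on its floor (0 for a healthy valve, the closure
  defect dc > 0 under IMI) whenever the gradient is adverse. The
  transmitral flow equation is ungated — regurgitation is possible —
  and carries an area-dependent impedance (R ∝ A⁻², L ∝ A⁻¹, anchored
  at the validated open-valve values) plus a convective term Q·Ȧ/A from
  the moving aperture.

Built-in presets: `healthy` (intact valve, dc = 0) and `imi`
(end-systolic LV elastance halved, dead volumes raised, dilated annulus
A_max = 1.3 cm², permanent closure defect dc = 0.2 cm²).

The discontinuous gates are integrated as a hybrid system: gate states
are held constant between zero-crossing events (valve opening/closing,
aperture floor/ceiling/liftoff) and the stiff integrator restarts at
each event, so valve switching is resolved to solver precision.

See `docs/methods.md` for assumptions, parameter provenance, numerical
choices and known limitations.

## Worked example

```bash
minicvs simulate --preset healthy --variant both --out-dir demo
```

runs both variants to their periodic steady state and writes, per
variant, a dense one-cycle trajectory CSV, a metrics JSON, the resolved
config, and a corner-by-corner comparison. The dynamic-valve metrics
(`demo/healthy_dynamic_mv_metrics.json`) read:

```
SV                  79.42    # stroke volume (ml), max − min LV volume
Vmin                47.44    # end-systolic LV volume (ml)
Vmax               126.86    # end-diastolic LV volume (ml)
t_open               0.455   # mitral opening time in the cycle (s)
t_close              0.925   # mitral closure time (s)
Qmt_max            424.0     # peak transmitral (E-wave) flow (ml/s)
regurgitant_volume   0.002   # reverse transmitral volume (ml) — none
```

so the healthy heart ejects ≈79 ml per beat between 47 and 127 ml, the
valve opens as the ventricle relaxes past the venous pressure and seals
again just before the next contraction. The comparison file shows the
two valve formulations agree at the four PV-loop corners to ≤0.62 ml.

The same run with `--preset imi` shows the insufficiency: the aperture
never falls below the 0.2 cm² defect, systole drives ≈ −185 ml/s of
backflow (≈40 ml regurgitant volume), the LV dilates (minimum volume
≈84 ml), the apparent stroke volume rises to ≈98 ml, and both
isovolumetric phases of the PV loop disappear (flagged per corner in
the metrics).

Library use mirrors the CLI:

```python
import minicvs as m

params = m.preset("imi")
res = m.run_to_steady_state(params)      # one converged cycle
met = m.cycle_metrics(res)
print(met.SV, met.Vmin, met.regurgitant_volume)
```

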