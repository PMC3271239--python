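# Methods

## Model structure

The circulation is closed: six stressed-volume chambers exchange blood
through four gated inertial valves (mitral mt, aortic av, tricuspid tc,
pulmonary pv) and two Ohmic vascular beds (systemic R_sys between aorta
and vena cava, pulmonary R_pul between pulmonary artery and veins).
State vector: six chamber volumes, four valve flows, and — in the
dynamic-valve variant — the mitral aperture area A and its rate Ȧ.
Total stressed volume is conserved exactly by construction (the flow
terms telescope), and the test suite verifies conservation to well
below 0.01 ml over 30 cycles for both variants and both presets.

Atria are not modelled; ventricular filling is purely passive (E-wave
only). Cycle boundaries sit at integer multiples of the driver period
D_1 = 60/HR, so all reported times share the driver's phase frame (peak
activation at t = C_1 = 0.27 s).

### Ventricular interaction

The septum is an active chamber in trans-septal pressure balance:
V_spt solves P_spt(V_spt) = P_lvf(V_lv − V_spt) − P_rvf(V_rv + V_spt),
each pressure the usual activation blend of ESPVR and EDPVR. The
residual is strictly increasing in V_spt, so the root is unique; it is
found by warm-started Newton iteration with an analytic slope (absolute
residual < 1e−10 mmHg), falling back to bracketed brentq on
[V_d,spt ± 50] ml. The pericardium adds an EDPVR-only pressure on
V_lv + V_rv, plus the thoracic offset P_th, to both ventricles.
P_th also offsets the pulmonary artery and pulmonary veins; aorta and
vena cava take none. A config switch (`numerics.interaction`) freezes
the septum at its zero-pressure volume and reduces the pericardial
pressure to P_th, which makes each ventricle collapse exactly onto its
free-wall relation (tested).

### Mitral aperture dynamics

The aperture is a forced oscillator with natural frequency ω = 30 rad/s
and damping rate D = 10 s⁻¹:

    dȦ/dt = ω²(A_max − A)·K_s·ΔP − 2D·Ȧ − ω²A,   ΔP = P_pu − P_lv,

gated by H(H(ΔP) + H(A − dc) − 0.5). Two interpretive decisions were
forced by internal inconsistencies in the printed formulation, and both
are deliberate design choices of this package:

1. **Damping rate, not ratio.** Read as a damping *ratio* ζ = 10 the
   oscillator is heavily overdamped (slow mode ≈1.5 s⁻¹, τ ≈ 0.67 s): the
   aperture can neither open nor close within a diastole, the valve
   stays open into systole, and a healthy heart regurgitates ~10 ml per
   beat — contradicting everything the model exists to reproduce. With
   the damping *rate* 2DȦ (ζ = D/ω = 1/3, underdamped) the leaflets
   open in tens of milliseconds and snap shut during E-wave
   deceleration; the "eigen frequency" name and the positivity gate
   (which only matters if A actually dives toward zero) both make sense
   only in this regime.

2. **Forcing gain in SI pressure.** The static gain K_s = 0.05 per mmHg
   caps the equilibrium opening at A_max·K_sΔP/(1 + K_sΔP) ≲ 0.25·A_max
   under physiological gradients (~5 mmHg), choking transmitral flow to
   a few tens of ml/s. The presets therefore apply the gain to the
   gradient expressed in pascal (effective gain 6.6661 per mmHg), under
   which the valve opens to ≈A_max and the dynamic model reduces to the
   validated diode model whenever the valve is open — which is exactly
   the behaviour the baseline comparison demands (corner agreement
   ≤0.62 ml) and what makes the IMI leak physiological.

The aperture is confined to [floor, A_max]: a hard floor at 0 (and at
the closure defect dc under an adverse gradient), and a ceiling at
A_max where the leaflets lose their kinetic energy (A_max is the
maximal area the aperture can reach; the bare ODE would overshoot it by
~50% when underdamped). All three bounds are event-handled, not
clamped per step.

### Mitral impedance laws

Two area-dependent impedance laws are available:

* `anchored` (default): R_mt(A) = R_open·(A_ref/A)²,
  L_mt(A) = L_open·(A_ref/A), anchored at the validated open-valve
  values R_open = 0.0158 mmHg·s/ml, L_open = 7.6968e−5 mmHg·s²/ml at
  A_ref = 1.1 cm². At full opening the valve is exactly the validated
  diode's impedance; at the IMI defect (0.2 cm²) the leak resistance is
  ≈0.48 mmHg·s/ml, giving a systolic backflow of ≈−185 ml/s.
* `cylindrical`: the literal Poiseuille/blood-column forms
  R = 8πμl/A², L = ρl/A evaluated in SI (ρ = 1050 kg/m³,
  μ = 4e−3 N·s/m², column length l configurable) and converted at
  1 mmHg·s/ml = 1.33322e8 Pa·s/m³. Note that their ratio
  L/R = ρA/(8πμ) is independent of l and ≈1 s at physiological areas —
  an inertia-dominated regime two orders slower than the validated
  open-valve ratio (≈5 ms), which is why no single column length can
  reproduce both validated coefficients and why `anchored` is the
  default. Every division by A is regularised as A + ε
  (ε = 1e−4 cm², configurable).

## Parameters

All chamber, valve, driver and mitral-oscillator constants are the
published base values (healthy and remodelled-heart tables); they are
carried verbatim in the two presets. Quantities that the published
tables do not fix were set as follows:

| quantity | value | how chosen |
|---|---|---|
| E_ao | 0.6913 mmHg/ml | the validated source model's aortic elastance (the base table prints a truncated "0.0", which would zero aortic pressure) |
| R_sys | 1.2021 mmHg·s/ml | calibrated (with R_pul and stressed volume) so the healthy preset reproduces SV = 79.43 ml and min V_lv = 47.47 ml — the only two calibration observables |
| R_pul | 0.065 mmHg·s/ml | same calibration; physiological (~1 Wood unit) |
| stressed volume | 1672 ml total | same calibration; the preset initial volumes are each preset's own converged cycle-start distribution, so runs converge in a few cycles (the steady state is insensitive to the split — tested) |
| ρ, μ | 1050 kg/m³, 4e−3 N·s/m² | physiological constants (cylindrical law only) |
| l | 0.02 m | free geometric scale of the cylindrical law |
| ε | 1e−4 cm² | area regularisation floor |

Everything else reported by the package — valve timing, peak
transmitral flow, the entire IMI preset's volumes and regurgitation,
and the cross-variant corner agreement — is out-of-sample with respect
to that calibration.

## Numerics

* **Hybrid integration (default `discrete` mode).** The Heaviside
  gates make the RHS discontinuous, and the instantaneous gate H(Q)
  freezes flow exactly at Q = 0 — a surface an adaptive solver cannot
  step across (it chatters with ever-shrinking steps; we measured LSODA
  pinned at one time point for >1e6 evaluations). Each gated valve is
  therefore a two-state automaton: a closed valve reopens at an upward
  zero-crossing of its pressure gradient, an open valve closes at a
  downward zero-crossing of its flow (flow clamped to exactly 0), and
  LSODA (rtol 1e−7, atol 1e−8, max step 2 ms) restarts at every event.
  The aperture floor/ceiling/liftoff transitions are handled the same
  way; the freeze/liftoff pair carries a 1e−6 mmHg hysteresis band so
  root-finder noise in the septum solve cannot retrigger it while the
  gradient hovers at zero in diastasis.
* **Smoothed fallback (`smooth` mode).** Every H replaced by a logistic
  of steepness k = 500, no events. It reproduces the global
  hemodynamics (stroke volume to ~2%, volume conserved) but deviates at
  gate boundaries by construction — H(0) = 0 becomes 1/2, and the
  aperture floor is soft, so the area can drift ≈0.07 cm² below zero
  and valve timing shifts by up to tens of ms. It is a qualitative
  fallback, not the reference integrator.
* **Steady state.** Cycles repeat until the state at successive cycle
  starts changes by < 5e−4 relative (component-wise, floor 1.0 on the
  denominator), then one further cycle is emitted densely at 1 ms in
  cycle-local time. Halving the solver tolerances moves stroke volume
  and peak flow by < 0.5% and valve open/close times by < 1 ms
  (tested).
* **Metric extraction.** Event instants (valve opening/closing, PV
  corners) are located by linear interpolation between output samples;
  corners are flagged rather than dropped when an isovolumetric phase
  has disappeared (|ΔV| > 1 ml across the phase). Mitral timing uses
  the aperture trace with threshold dc + ε; stroke volume is
  max − min of V_lv over the cycle, the only definition that survives
  the disappearance of the isovolumetric corners under IMI.

## What the simulations do and do not show

The healthy dynamic-valve run reproduces its calibration targets
(SV 79.4 ml, min V_lv 47.4 ml), closes the mitral valve at 0.925 s
(reference 0.921 s), regurgitates nothing, and agrees with the
baseline diode model at all four PV corners to ≤0.62 ml. The IMI run —
entirely out-of-sample — reproduces the reference minimum LV volume to
0.8% (83.9 vs 83.2 ml) and overestimates the reference stroke volume by
5.4% (97.8 vs 92.8 ml), with a permanently open aperture (min A = dc)
and ≈40 ml of regurgitation per beat.

Known, quantified discrepancies against the reference simulation
values, none of which could be removed within the printed parameter
set (the relevant scans are part of the development record):

* The mitral valve opens at ≈0.455 s and the aperture peaks at
  ≈0.509 s (references: 0.589 s and 0.666 s). With the published driver
  (B = 80 s⁻², C = 0.27 s) and EDPVR/pericardium constants, the
  atrioventricular crossover at matched SV falls at activation
  ≈0.03–0.05, i.e. t ≈ 0.45–0.47 s; delaying it to 0.589 s would
  require the pulmonary-venous pressure to equal the fully relaxed LV
  pressure, which leaves no gradient to drive a 79 ml filling volume.
  The two requirements are mutually exclusive in this model family.
* Peak transmitral flow is ≈424 ml/s (reference 569.7 ml/s). With the
  aperture bounded by A_max, the open-valve resistance is bounded below
  by the validated 0.0158 mmHg·s/ml, so 569.7 ml/s needs a 9.0 mmHg
  peak gradient where the calibrated hemodynamics provide ≈6.7. The
  simulated value sits inside the 450–550 ml/s physiological range at
  its lower edge.
* Corner-wise *pressure* differences between the variants reach
  ≈1.1 mmHg (volumes agree to ≤0.62 ml): corner pressures are sampled
  at valve-event instants on steeply moving pressures, so a few-ms
  difference in detected opening between the two valve formulations
  maps to ~1 mmHg.

The model remains a lumped, atrium-less description: no A-wave, no
leaflet anatomy (the oscillator constants are effective, not
anatomical), no autonomic control, and valve dysfunction other than a
mitral closure defect is out of scope. Agreement on the synthetic
presets therefore says nothing about patient-specific prediction
without identification of the parameters from data.
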