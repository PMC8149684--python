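# Methods

## The circuit

The circulation is a closed loop of six sub-models: left atrium, left
ventricle, aortic valve, mitral valve, systemic circulation and pulmonary
circulation. The netlist (each element once, in its anatomical position):

```
pulmonary source Q_PV(t)  -->  node PA [C_PA]
node PA  -- R_PA -- R_PC -- L_PC -->  node PVC [C_PVC]
node PVC -- R_PVC -- R_PV -- L_PV -->  left atrium (elastance chamber)
LA  >| MV / |< MR >|  left ventricle (elastance chamber)
LV  >| AV / |< AR >|  node AO [C_ao]
node AO -- R_ao --> arterial junction [C_SAC]
junction -- R_ub --------------------> venous node (fixed P_CV0)
junction -- R_pda -- R_SA -- R_SV ---> venous node (fixed P_CV0)
```

The venous node is clamped at the central venous pressure P_CV0 = 4 mmHg;
the right heart is abstracted by the rectified-sine source
Q_PV(t) = Q_MPV·sin(πt/t_ee) for t ≤ t_ee (the ejection time), 0
otherwise, which delivers 2·Q_MPV·t_ee/π mL per beat.

Placement of the systemic compliance C_SAC is the one genuinely open
topology question (circuit diagrams of this model family are drawn, not
spelled out). We place it on the arterial junction where the upper-body
and descending branches split, for two reasons. First, physiology: both
compliances then sit upstream of the peripheral resistance (windkessel
arrangement), giving a diastolic decay time ≈ (C_ao + C_SAC)·(R_pda +
R_SA + R_SV) ≈ 2 s and diastolic pressures in the normal range at the
reference parameter values; with C_SAC downstream of R_SA the arterial
pool drains through R_SV = 0.05 mmHg·s/mL with a 0.1 s time constant and
diastolic pressure collapses to ~10–30 mmHg. Second, identifiability:
with the two compliances on adjacent nodes (separated only by
R_ao = 0.05) the cuff pulse pressure constrains their *sum* well, which
is what makes the pressure fit's combined compliance meaningful (see
below).

## Chambers

Both chambers use the double-Hill elastance
E(t) = N·[(t/τ₁)^m₁/(1+(t/τ₁)^m₁)]·[1/(1+(t/τ₂)^m₂)] + E_min with
N = (E_max − E_min)/2 and τᵢ given as fractions of the heart period T.
Reference values: LV E_max 2.1, E_min 0.06 mmHg/mL, m₁ 1.32, m₂ 27.4,
τ₁ 0.269T, τ₂ 0.452T; LA E_max 0.17, m₂ 13.1, τ₁ 0.110T, τ₂ 0.18T.
Both brackets lie in [0, 1], so E(0) = E_min exactly and
E ≤ (E_max+E_min)/2. Time is taken modulo T inside the evaluation, so
callers never wrap.

The reference parameters place both activations at t = 0. Atrial
contraction must instead precede ventricular systole, so the LA elastance
is evaluated on a shifted axis t − `la_phase_frac`·T (mod T), default
0.85·T: atrial activation then lands late in diastole, producing the
physiological A wave just before mitral closure. The shift is exposed as
a parameter because no timing datum constrains it.

Unloaded volumes V₀ (defaults: LV 10 mL, LA 5 mL) only translate the
volume axis — pressure depends on V − V₀ alone — so the measured
end-diastolic volume is anchored exactly by one post-fit shift
V₀ ← V₀ + (EDV_measured − EDV_simulated) and a single re-solve.

## Valves

Forward branches (AV, MV) and optional regurgitant branches (AR, MR) are
series inertance + flow-dependent Bernoulli resistance elements carrying
the net pressure gradient; aortic-side coefficients use the energy-loss
coefficient E_LCo = EOA·A/(A − EOA) (A = ascending-aorta area for AV,
LVOT area for AR), mitral-side ones the raw EOA with the inertance
constant M_MV = 0.53 g/cm². Coefficients are evaluated in CGS and
converted once through 1 mmHg = 1333.22 dyn/cm². A regurgitant branch is
built only when its orifice area was measured.

Each branch is an ideal diode: flow is non-negative along the branch
orientation. In the production integrator the gate is implemented as a
complementarity projection — closed branches with adverse pressure have
zero flow derivative, and any undershoot is clamped to zero after each
step (undershoot is then exactly 0). A smooth variant (reverse regime =
10⁴ mmHg·s/mL leak resistance blended over ~0.05 mL/s; back-leak
< 0.01 mL/cycle) exists solely for the implicit cross-check integrator,
because discontinuous gating defeats Newton-based step control.

## Integration to periodic steady state

The 12 ordinary differential equations (2 chamber volumes, 4 capacitor
pressures, 4 gated valve flows, 2 pulmonary inductor flows) are advanced
by classical fixed-step RK4 at Δt = 0.1 ms (the grid of the emitted
waveforms; the fastest local time constants are ≥ 4 ms, so the step is
well inside the stability region and step-halving changes the periodic
solution by < 10⁻⁵ relative). The whole cycle loop is JIT-compiled with
numba. Starting from zeroed capacitor pressures and inductor flows, the
circuit is cycled until the start-of-cycle state is periodic to a
relative L∞ tolerance of 10⁻⁶ (max 150 cycles). The cycle-start state
obeys a contractive fixed-point map whose slowest mode (the large
pulmonary venous compliance, C_PVC = 40 mL/mmHg) decays only ~7% per
cycle, so the dominant mode is removed every few cycles by Aitken-style
geometric extrapolation (eigenvalue estimated from successive cycle
differences); the convergence criterion is always evaluated on raw,
un-extrapolated cycle pairs. Cold-start convergence takes ~30 cycles,
warm-started solves inside the optimisers 2–15. Non-convergence within
the cycle budget is a flagged result, not an exception; only non-finite
state aborts.

An independent cross-check integrates one cycle from the same converged
state with the variable-step implicit Radau IIA scheme on the
smooth-diode field; pressures agree to < 0.1 mmHg and cycle volumes to
< 0.05%. Repeated variable-step cycling is deliberately not offered: the
ideal-diode switching creates sliding modes on which implicit step
control either stalls or converges to a spurious closed-valve branch.

## Patient-specific estimation

Stage 0 — fixed tuning. R_ub is solved (bracketed root-find in
[0.1, 100] mmHg·s/mL) so the upper-body branch carries 15% ± 0.5% of
systemic flow under a healthy baseline configuration (normal valve
areas, 70 mL stroke volume, 120/80 mmHg), then held fixed for all
patients. The serial-path seed R_SA ≈ TSR − (R_ao + R_pda + R_SV) with
TSR = MAP/CO and MAP = DBP + (SBP − DBP)/3 (standard cuff estimator; the
model never sees a measured mean pressure) starts the pressure fit.

Stage 1 — flow. Q_MPV is fitted so the cycle integral of the aortic
valve flow equals the measured forward LVOT stroke volume. The map is
monotone and nearly proportional (the closed form π·SV/(2·t_ee) is the
seed), so a damped proportional update converges in 2–4 steady solves to
a residual ≤ 0.1%.

Stage 2 — pressure. (R_SA, C_SAC, C_ao) are fitted by bound-constrained
trust-region-reflective least squares (tolerances 10⁻⁶, ≤ 50 steady-solve
evaluations) on the residuals (max P_ao − SBP, min P_ao − DBP), starting
from the reference initial values (0.8, 2, 0.5). Two cuff pressures
cannot determine three parameters: solutions form a one-dimensional
manifold along which the compliance split C_SAC/C_ao varies freely. A
weak third residual, 2.0·(log(C_SAC/C_ao) − log 4) mmHg per log-unit,
regularises the split toward the reference 4:1 ratio; it resolves only
the direction the data cannot see, and the pressure residuals still
converge to ~10⁻⁴ mmHg. With this topology and regularisation, a
noise-free synthetic cohort shows median recovery errors of ~10⁻⁵ for
Q_MPV, < 0.5% for R_SA and 3–4% for the combined compliance
C_ao + C_SAC; the split itself is recovered only when the truth's split
is near the reference ratio, which is the honest statement of what cuff
pressures contain.

Stage ordering is enforced (the pressure fit refuses to run without a
completed flow fit). With regurgitant branches the pressure fit shifts
the regurgitant volume and hence the forward stroke volume, so the two
stages are alternated up to twice before the final verification solve.
Convergence is declared only when |SV error| ≤ 1% and both pressure
errors ≤ 1 mmHg at that final solve; otherwise the achieved residuals
are reported on the result object.

## Hemodynamic metrics

Ejection fraction (EDV − ESV)/EDV (reduced below 0.41); LV workload as
the shoelace area of the closed P-V loop, 1 mmHg·mL = 1.33322·10⁻⁴ J;
systemic arterial compliance as SV/(SBP − DBP) in mL/mmHg (the standard
stroke-volume-to-pulse-pressure estimator; the formula is recorded in the
metrics output because other SAC estimators exist, and indexing to body
surface area is left to the caller since no BSA input exists); E/A as the
ratio of the two largest local maxima of transmitral velocity Q_MV/EOA_MV
separated by ≥ 0.05·T, earlier peak = E, with a single-peak flag when the
A wave is fused or absent (normal band 0.8–2). Transvalvular gradients
are phase-restricted: aortic = max over Q_AV > 0 of P_LV − P_ao (mean
gradient = ejection-phase average; > 40 mmHg flags severe stenosis),
transmitral = max over Q_MV > 0 of P_LA − P_LV; a simplified-Bernoulli
4·v² estimate from the peak transvalvular velocity is reported alongside
the instantaneous circuit difference, since clinical gradients are
usually velocity-derived. TAWSS = (1/T)∫|τ|dt (trapezoidal) and the
vortex sphericity index D₂/D₁ (> 2 normal) operate on externally supplied
series/dimensions — this package computes no 3-D flow.

## Tissue kernels and Young's-modulus calibration

The passive LV wall is an isotropic St. Venant-Kirchhoff solid:
Σ = λ·tr(E)I + 2µE with E = ½(FᵀF − I) and σ = (1/det F)·F·Σ·Fᵀ. The
deformation-gradient convention is F = I + (∇u)ᵀ — note the transpose;
many texts define F = I + ∇u. Robin interface-pressure coefficients for
partitioned fluid-structure coupling use the dilatational-wave thickness
h_s = Δt·√((λ+2µ)/ρ_s) and α = ρ_s·h_s/ρ_fluid. Defaults ν = 0.3 and
ρ_s = 1050 kg/m³ are exposed configuration (no measurement constrains
them here).

Calibration of the Young's modulus against a diastolic P-V limb is
implemented on a declared surrogate: a thin-walled spherical SVK membrane
(equibiaxial stretch λ_s = (V/V₀)^⅓, plane stress through the wall,
Laplace relation P = 2σ_θh/R). Shell pressure is linear in E and strictly
increasing in V, so the signed mean mismatch is monotone in E and a
bracketing root-find both locates and certifies the least-squares
optimum; self-generated targets are recovered to ~10⁻¹⁰ relative. The
surrogate stands in for a meshed ventricle so the *procedure* is testable
at desk scale; it is not a 3-D solid solver, and calibrated moduli carry
the surrogate's geometric idealisation.

## Synthetic patients

The generator emulates a Doppler + cuff measurement session on a patient
whose circuit is known: anatomy and timing are sampled within
physiological ranges (HR 50–90 /min, stroke volume 40–100 mL, ejection
fraction of the period 0.28–0.38, EOA_AV 0.6–2.5 cm², EOA_MV 2–5 cm²,
LVOT diameter 1.8–2.6 cm, aortic diameter 2.7–3.6 cm, regurgitant
orifices 0.05–0.4 cm² with configurable probability); the free circuit
parameters (R_SA, C_SAC, C_ao) are drawn log-uniformly within ±50% of
their reference initial values and Q_MPV is set by the closed form to
deliver the sampled stroke volume. The truth circuit is simulated to
steady state and the "measurements" read off exactly as a sonographer
would take them (stroke volume from the aortic forward volume, SBP/DBP
from the aortic pressure extrema, EDV/ESV from the volume trace, VTIs
consistent with areas); optional noise corrupts stroke volume
(multiplicative) and pressures (additive). Generation is deterministic
per seed; non-convergent draws are resampled with bounded retries.

What the generator does *not* emulate — and therefore what recovery
tests cannot show: model mismatch (real hearts are not double-Hill
elastances with these fixed pulmonary constants), measurement bias
(Doppler angle errors, cuff-to-central pressure transfer), beat-to-beat
variability, and pathologies outside the sampled ranges. Recovery
results certify the estimation machinery, not clinical accuracy.

The sensitivity mode perturbs the measured forward stroke volume by ±20%
(propagated the way the pipeline sees it, through a Q_MPV refit) and each
fixed pulmonary constant by ±20% (direct perturbation), and compares the
induced relative changes in peak LV pressure and peak LV volume; the
stroke-volume input dominates every pulmonary constant by orders of
magnitude, confirming that the single flow input carries the model.

## Problem sizes and runtimes

Default cycles use 0.1 ms steps (≈ 7–12·10³ samples at HR 50–90). The
test suite exercises cohorts of up to 20 noise-free and 20 noisy
synthetic patients (a full two-stage fit takes ~2–4 s); the acceptance
script uses a 10-patient noise-free cohort. All optimiser loops reuse the
previous steady state as the warm start for the next solve.

## Known limitations

- Single-compartment chambers; no regional wall mechanics, no baroreflex,
  no respiratory modulation, no right-ventricle chamber (the rectified
  sine is an open-loop stand-in).
- The compliance split C_SAC/C_ao is not identifiable from cuff pressures;
  only the regularised split is reported (see estimation).
- The atrial phase shift is a modelling choice, not a measurement.
- Tissue calibration uses the spherical-shell surrogate; the interface is
  pluggable for a 3-D solid solver but none is included.
- Valve gating is ideal-diode with a projection scheme; leaflet dynamics
  and paravalvular-leak geometry are out of scope (a leak can only be
  posed as an extra regurgitant branch by the caller).
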