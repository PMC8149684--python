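# lumpedheart

Non-invasive, patient-specific simulation of left-heart and circulatory
hemodynamics from routine Doppler echocardiography and a blood-pressure
cuff.

Quantities clinicians need for valvular/ventricular/vascular disease
work-ups — instantaneous chamber pressures, transvalvular gradients, the
pressure-volume loop and its workload, systemic arterial compliance —
cannot be measured non-invasively. `lumpedheart` reconstructs them with a
closed-loop lumped-parameter (0-D) model of the left atrium, left
ventricle, the four valve branches and the systemic and pulmonary beds,
whose free parameters are estimated per patient from a handful of
reliably measurable inputs: forward LVOT stroke volume, heart period and
ejection time, valve effective orifice areas, vessel diameters, chamber
volumes, and cuff systolic/diastolic pressures. It is aimed at
cardiovascular-modelling researchers and methodologists who need a fast,
fully testable 0-D engine — for example as the boundary-condition driver
of a 3-D fluid-structure model, for which pointwise St. Venant-Kirchhoff
tissue kernels and Robin interface-pressure coefficients are included.

## Model

Each chamber couples pressure to volume through a double-Hill
time-varying elastance

```
E(t) = N · [(t/τ₁)^m₁ / (1 + (t/τ₁)^m₁)] · [1 / (1 + (t/τ₂)^m₂)] + E_min,
N = (E_max − E_min)/2,      P(t) = E(t)·(V(t) − V₀)
```

Valves are gated nonlinear branches carrying the net transvalvular
pressure gradient; for the aortic side

```
ΔP = [2πρ/√(E_LCo)]·dQ/dt + [ρ/(2·E_LCo²)]·Q²,
E_LCo = EOA·A_AO/(A_AO − EOA)
```

(energy-loss coefficient accounting for pressure recovery), and for the
mitral side the inertance term is M_MV/EOA with M_MV = 0.53 g/cm². The
right heart is abstracted as a rectified-sine pulmonary flow source of
amplitude Q_MPV. Estimation runs in two sequential response
optimisations: Q_MPV is fitted so the model reproduces the measured
forward LVOT stroke volume, then (R_SA, C_SAC, C_ao) are fitted so the
maxima/minima of the simulated aortic pressure equal the cuff
systolic/diastolic pressures. See `docs/methods.md` for the full netlist,
parameter table provenance and numerical choices.

## Worked example

No clinical records ship with the package; the synthetic-patient module
generates records with known ground-truth circuit parameters:

```
$ lumpedheart synth --n 1 --seed 42 --out cohort
$ lumpedheart fit --patient cohort/patient_000.json --out fit0
$ cat fit0/fit_report.txt
patient            : synth-42-000
converged          : True
stroke volume error: +0.0001 mL (target 91.52 mL)
SBP error          : -0.0001 mmHg (target 112.6)
DBP error          : -0.0000 mmHg (target 74.9)
cycles to steady   : 2
fitted Q_MPV       : 598.870 mL/s
fitted R_SA        : 0.6498 mmHg·s/mL
fitted C_SAC       : 1.9573 mL/mmHg
fitted C_ao        : 0.4893 mL/mmHg
tuned R_ub         : 5.1000 mmHg·s/mL
```

The fit reproduced this patient's measured stroke volume to 0.0001 mL and
the cuff pressures to within 0.001 mmHg by adjusting the pulmonary source
amplitude (598.9 mL/s), the systemic artery resistance and the two
arterial compliances. `fit0/metrics.json` then reports the derived
hemodynamics, e.g. for this patient EF 0.362 (reduced, < 0.41), LV
workload 1.25 J, systemic arterial compliance 2.43 mL/mmHg, peak/mean
aortic-valve gradient 29.0/14.4 mmHg and transmitral E/A ratio 0.95 —
quantities otherwise requiring catheterisation. `fit0/waveforms.csv`
holds the full steady-state cycle (pressures, volumes, flows on a 0.1 ms
grid) for plotting P-V loops or driving downstream models.

The same pipeline is scriptable from Python (`lumpedheart.fit_patient`,
`lumpedheart.generate_cohort`, ...), and `lumpedheart report --cohort
cohort/` fits a whole synthetic cohort and tabulates how well the known
generating parameters are recovered.

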