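# shuntloop

Closed-loop lumped-parameter (0D) hemodynamics of the Blalock–Taussig (BT)
shunt circulation in single-ventricle physiology.

After a Stage-I Norwood procedure for hypoplastic left heart syndrome, the
pulmonary arteries are supplied entirely through a 3.5–4 mm BT shunt from
the innominate artery. Whether that shunt has narrowed, and how a modified
(flared) shunt design would change pulmonary pressures and flows, are
questions a 0D circulation model can address from routine catheterization
and PC-MRI data. `shuntloop` provides, for researchers in computational
cardiovascular physiology:

- a **netlist-defined circuit simulator** — resistors, capacitors,
  inductors, diode valves and a time-varying-elastance ventricle over
  named pressure nodes, integrated implicitly (backward Euler, valve
  switching by step rejection) to periodic steady state;
- the **closed-loop single-ventricle circulation**: three-element
  Windkessel outlets and venous sections, atrial septal defect,
  aortopulmonary collaterals, and a reduced-order resistive surrogate for
  the image-based arterial domain;
- the **patient-specific elastance pipeline**: integrate the neo-aortic
  valve flow, divide the ventricular pressure by the volume, extrapolate
  diastole with a single Gaussian, Fourier-smooth, and rescale to preserve
  the peak;
- **shunt-occlusion inference**: a Hagen–Poiseuille closed form
  `s = (R_ref/R_target)^(1/4)` and an authoritative iterative route that
  bisects on the diameter scale in closed-loop simulation;
- a **comparison harness** for the 16 clinical indices (10% relative rule;
  pulmonary-artery pressures accepted within the clinically recorded
  12.9–16.5 mmHg range) and percent-change tables between shunt designs;
- a **virtual-patient generator** so every stage is testable as a
  parameter-recovery problem without any external data.

## Model

Each vascular outlet obeys the three-element Windkessel relation

    C·Rd·dP/dt + P − Pd − Q·(Rp + Rd) − Rp·Rd·C·dQ/dt = 0,

whose steady state is `P = Pd + (Rp+Rd)·Q` and input impedance
`Z(ω) = Rp + Rd/(1 + iωRdC)`. The single ventricle is a time-varying
elastance chamber `P = E(t)·(V − V0)` with diode valves
(open: `ΔP = R·Q + L·dQ/dt`; closed: `Q = 0`). In the closed loop the
distal pressure of every Windkessel is a solved circuit node, so flow
continuity is enforced around the whole circulation. Units throughout:
mmHg, ml/s, ml, s.

## Worked example

The effective shunt diameter implied by measured resistances, via the
closed-form d⁻⁴ route:

```
$ shuntloop occlusion --r-ref 2.1 --dp 41.7 --q 9.7
method poiseuille_scaling
diameter_scale 0.836014
diameter_reduction_pct 16.4
area_occlusion_pct 30.11
effective_diameter_mm 2.926
```

Here 41.7 mmHg / 9.7 ml/s = 4.3 mmHg·s/ml is the measured effective
resistance, 2.1 mmHg·s/ml the as-implanted reference; the d⁻⁴ law says
the diameter scale that raises 2.1 to 4.3 is 0.836 — a 16% reduction.
(The closed form depends on which resistances the law is applied to;
`shuntloop occlusion --simulate` runs the authoritative bisection in the
closed loop instead.)

Running the closed loop itself:

```
$ shuntloop simulate --model figure1_baseline --dt 1e-3 --cycles 40 --tol 2e-3
aortic_root_mean_pressure                31.142
...
LPA_mean_pressure                        12.110
RPA_mean_pressure                        12.119
shunt_mean_flow                           5.436
```

prints the 16 comparison indices of the converged cycle (mean pressures
in mmHg, mean flows in ml/s). Swapping to `--model figure1_flared`
(shunt resistance 3.5 → 3.3 mmHg·s/ml) raises pulmonary pressures and
shunt flow, the qualitative benefit attributed to flared shunt designs.
The absolute operating point depends on assumptions documented in
`docs/methods.md` (heart rate, elastance constants, initial venous
pressures), not on fitted patient data.

Python API equivalents live in `shuntloop.config` (`run_model`),
`shuntloop.elastance` (`build_elastance`), `shuntloop.occlusion` and
`shuntloop.compare`.

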