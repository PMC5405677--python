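# Methods

## Model

The circulation is a closed-loop 0D (lumped-parameter) circuit over named
pressure nodes with one global zero-pressure reference. Element laws:
resistor `Q = ΔP/R`; capacitor `Q = C·dΔP/dt`; inductor `ΔP = L·dQ/dt`;
diode valve `ΔP = R·Q + L·dQ/dt` when open and `Q = 0` when closed;
elastance chamber `P = E(t)·(V − V0)` with `dV/dt` equal to the net
nodal inflow. Units: pressure mmHg, flow ml/s, volume ml, time s,
resistance mmHg·s/ml, compliance ml/mmHg, inertance mmHg·s²/ml.

The patient circuit chains: elastance ventricle → neo-aortic valve →
aortic root → reduced-order arterial surrogate (five systemic branches,
BT shunt, two pulmonary branches) → seven arterial three-element
Windkessels → four venous Windkessel-like sections → two
constant-compliance atria joined by an atrial-septal-defect resistor →
atrioventricular valve → ventricle, plus two aortopulmonary collateral
resistors. In the closed loop every Windkessel's distal pressure is a
solved node, not a constant.

### Windkessel form

The three-element Windkessel satisfies
`C·Rd·dP/dt + P − Pd − Q·(Rp+Rd) − Rp·Rd·C·dQ/dt = 0`, with steady state
`P = Pd + (Rp+Rd)·Q` and impedance `Z(ω) = Rp + Rd/(1+iωRdC)`. Variant
sign conventions of this relation circulate in the literature; the form
here is the one whose steady state and impedance limits the solver's
oracle tests check directly.

## Time integration

First-order implicit (backward Euler) discretization. Unknowns are the
node pressures, the flows of inertial/source branches, and the chamber
volumes; equations are one Kirchhoff current balance per node plus one
element law per flow/volume unknown. With frozen valve states every law
is linear, so the per-step Newton iteration collapses to a single direct
dense solve (`numpy.linalg.solve`; the systems here have ~10–30
unknowns). Backward Euler is unconditionally stable, which matters for
the stiff venous compliances (up to 285 ml/mmHg) against millisecond
valve dynamics, and makes valve-event handling simple.

Valve switching is by step rejection: after each solve, a closed valve
opens if its upstream-minus-downstream pressure is strictly positive and
an open valve closes if its flow is ≤ 0; the step is re-solved after any
switch. Ties (ΔP = 0) keep the current state; each valve may switch at
most once per step, and exceeding the guard is counted as a chatter
event in the diagnostics rather than an error.

Defaults: dt = 1e-4 s; cycle period 0.46 s (a typical 4-month-old heart
rate — no patient heart rate is recorded anywhere in the source data, and
all flow targets are cycle means, so the period is a free configuration
parameter); initial condition 10 mmHg at every node with valves closed
and the ventricle at its configured end-diastolic volume. Periodic
convergence is declared when the largest relative change of any
cycle-mean node pressure between consecutive cycles falls below 1e-3
(`tol=inf` returns the first cycle); pressures beyond ±1000 mmHg abort
with diagnostics. Because the discretization is consistent with the node
balances, total stored volume (chamber volumes plus `C·ΔP` over
capacitors) is conserved to machine precision per step in a closed loop;
the test suite asserts < 0.1 % drift per cycle and < 1e-6 ml/s Kirchhoff
residual, and a step-halving check (2e-4 vs 1e-4 s) bounds the
discretization error of cycle means below 0.5 %. Test and recovery
studies run closed loops at dt = 2e-4 s on that basis.

## Parameterization

The packaged tables carry the printed Windkessel constants of the seven
arterial outlets (RC, LC, RS, LS, DAo, RPA, LPA), the four venous
sections (SVC, IVC, RPV, LPV) and the heart/shunt scalars (valve
open-resistances and inertances, two collateral resistances, ASD
resistance), loaded bit-exactly from `data/figure1_params.json`.

Quantities the source tables do not provide are package assumptions,
chosen once for infant-scale physiology and kept configurable:

- atrial compliances (2.0 ml/mmHg each) and atrial unstressed state;
- ventricular elastance constants for the builtin closed-loop models
  (E_min 0.2, E_max 3.0 mmHg/ml, peak at 0.15 s, Gaussian width 0.05 s,
  V0 = 0, EDV 38 ml);
- uniform 10 mmHg initial pressures. The venous compartments are so
  compliant that their pressures barely move from this value over a run,
  so the initial pressure effectively sets the venous operating point and
  total stressed volume (neither is printed anywhere).

Consequently the builtin loop's absolute operating point is *not* a
patient fit; all quantitative validation is against printed arithmetic
and synthetic ground truth, and the baseline-vs-flared comparison is
interpreted at sign level.

### Collateral wiring

The drawn circuit does not make the collateral attachment nodes legible.
With the printed resistances (0.097 and 0.05 mmHg·s/ml), attaching the
collaterals between systemic *arterial* (~50 mmHg) and pulmonary
(~12–16 mmHg) nodes would drive hundreds of ml/s through them —
two orders above the few-ml/s collateral flows the source reports. The
package therefore attaches them at the venous-side ends of the named
beds: Collateral 1 from the descending-aorta drain to the right pulmonary
venous entry, Collateral 2 from the arch-branch drain (SVC entry) to the
right pulmonary arterial entry, which yields few-ml/s collateral flows at
the printed resistances. Both endpoints are configurable
(`build_patient_circuit(..., collateral_endpoints=...)`).

### Arterial-domain surrogate

The image-based 3D arterial segment is replaced by eight series
resistors. Great-vessel branch resistances default to 1e-3 mmHg·s/ml
(negligible against the outlet Windkessels). The shunt branch defaults to
the *empirical* effective resistance (mean trans-shunt gradient over mean
flow: 3.5 mmHg·s/ml occluded baseline, 3.3 flared, 2.1 as-implanted)
rather than the Hagen–Poiseuille value of the bare 3.5 mm × 14 mm tube
(~0.11 mmHg·s/ml): most of the real pressure loss arises from
anastomosis, entrance and inertial effects a 0D tube law cannot
represent. This is the central fidelity compromise of the desk-scale
model. Poiseuille mode (`R = 128μL/(πd⁴)` plus a configurable
anastomosis loss) is available for diameter-scaling studies, and both
modes scale as d⁻⁴ in the diameter scale factor. The Reynolds number
uses the cross-section mean velocity `Q/(πd²/4)`; the occluded diameter
defaults to 0.78 × nominal (the printed 2.71 mm and the printed Re are
consistent with 2.73 mm; the 0.02 mm discrepancy is noted, not resolved).

## Elastance pipeline

`V(t) = EDV − ∫Q dτ` (trapezoidal) over the cycle; the ejection window is
`Q > 1 %` of peak flow (first contiguous run containing the peak);
`E_sys = P/(V − V0)` on that window with V0 defaulting to 0 (the
derivation divides pressure by volume directly; a nonzero unstressed
volume is configurable). Diastole is filled by least squares
(`scipy.optimize.curve_fit`) with a circular-time Gaussian plus constant
offset `E_min + A·exp(−d(t,t0)²/2σ²)`; the offset floor (0.05 mmHg/ml)
exists because a pure Gaussian decays to zero, which would force
identically zero diastolic ventricular pressure. "Fourier smoothing" is a
hard truncation of the discrete Fourier series to 10 harmonics (C^∞,
hence C¹, and idempotent), followed by a global rescale that restores the
pre-smoothing peak exactly.

Alignment of separately recorded traces shifts the volume/flow pair so
ejection onset coincides with the pressure upstroke landmark (time of
peak dP/dt). `build_elastance` does **not** align by default: traces
produced on a shared acquisition clock — including all virtual-patient
recordings — need no shift, and the landmark pair is only coincident up
to the isovolumic-contraction interval, so blind alignment of
already-synchronous traces would bias the systolic segment.

## Occlusion inference

Closed form: `scale = (R_ref/R_target)^(1/4)`, with
diameter-reduction % = 100·(1−s) and area-occlusion % = 100·(1−s²)
exactly. Applied to the whole-path effective resistances 2.1 → 4.3 this
gives ≈16 % reduction — deliberately *not* forced to agree with the
geometric narrowing estimate of 22 %, because the closed form depends on
which resistance the d⁻⁴ law is applied to and the original choice is
not recoverable. The iterative route is authoritative: bisection on the
diameter scale in [0.3, 1] until the simulated mean trans-shunt gradient
and flow are both within tolerance (default 10 %) of the targets. The
bisection *direction* is steered by the simulated effective resistance
gradient/flow — strictly decreasing in scale and asserted so at the
bracket ends — because in a closed loop the gradient itself is nearly
flat in scale (resistance rises while flow falls), which makes
gradient-bisection ill-conditioned. `tol = 0` is unsatisfiable in
floating point and yields a non-convergence report once the bracket
collapses below 1e-3. Successive bisection runs warm-start from the
previous converged state.

## Comparison harness

Sixteen indices: aortic-root mean/systolic/diastolic/pulse pressure and
mean flow; LPA and RPA mean pressure; mean flows in DAo, LPA, RPA, SVC,
IVC, RPV, LPV, ASD and shunt. Percent error uses the measured value as
denominator; the pass rule is 10 % relative, except LPA/RPA mean
pressures, which pass anywhere inside the recorded 12.9–16.5 mmHg span
(inclusive): the recordings themselves put the two PA means 3.6 mmHg
apart, wider than the model can reproduce. Only the indices quoted
numerically in the source are filled in the packaged target table; the
rest are null placeholders and skipped by the scorer. Report percentages
round to the nearest integer, halves away from zero. Recomputing the
published flaring tables from their printed means reproduces every
printed integer percent except the LPA flow (3.6 → 3.9 ml/s computes to
8 %, printed as 9 %), which the report flags as a source rounding
artifact rather than adjusting inputs to match.

## Virtual patients

The generator simulates an elastance ventricle with known Gaussian E(t)
ejecting through a valve into a three-element Windkessel (Rp 0.6, Rd 4.5,
C 1.2, Pd 6 mmHg) and refilling from a 7 mmHg venous reservoir — values
chosen to put arterial pressure near 50–60 mmHg and mean outflow near
10 ml/s, the magnitudes of this circulation, without claiming unprinted
patient values. Its "recordings" are the converged cycle's valve flow and
ventricular pressure resampled to 1 ms; measurement noise is
multiplicative Gaussian on the pressure only (catheter traces are the
noisier signal; PC-MRI flows are already cycle-averaged), fully
deterministic under a seed. Closed-loop target tables come from running
the packaged circuit at a known shunt diameter scale.

What the generator does *not* emulate: beat-to-beat variability,
respiratory modulation, baseline drift, flow-measurement noise, imaging
resolution effects, or any 3D flow feature (jets, recirculation,
high-frequency PA oscillations). Passing recovery tests therefore shows
the pipelines are correct inverses of the model class, not that they are
robust to every artifact of real recordings.

## Known limitations

- No 3D Navier–Stokes coupling; junction losses, Womersley effects and
  turbulence are outside the model class, which is why empirical shunt
  resistances are the default.
- The closed loop's absolute operating point rests on assumed elastance,
  atrial and initial-pressure values; design comparisons should be read
  as directional.
- Occlusion is represented as an equivalent uniform narrowing; spatially
  resolved stenosis shapes are out of scope.
- Backward Euler is first-order; the dt-halving test bounds the error at
  the defaults, but studies needing high-order accuracy should reduce dt.
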