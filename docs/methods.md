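# Methods

## The model

`fetalflow` implements a lumped-parameter (0D, electrical-analog) model of
the fetal arterial circulation. The arterial tree is reduced to 14 named
segments — ascending aorta, aortic isthmus, descending aorta, ductus
arteriosus, main/right/left pulmonary arteries, brachiocephalic trunk,
left/right subclavian, left/right common carotid and left/right internal
carotid arteries — each represented by a series resistor–inductor carrying
the segment flow with a shunt capacitor at its distal end:

    R = 8 μ l / (π r⁴)        (Poiseuille resistance)
    L = ρ l / (π r²)          (blood inertance)
    C = 3 π r³ l / (2 E h)    (thin-wall vessel compliance)

with `l`, `r` the segment length and radius, `μ = (1.15 + 0.075·GA)/100`
poise the gestational-age-dependent blood viscosity, `ρ = 1.05 g·cm⁻³` the
blood density, `h = 0.15 r` the wall thickness and `E` the segment Young's
modulus (7.5, 9.0 or 13.5 ·10⁵ dyn·cm⁻²). Lengths and diameters grow
linearly with gestational age; the regression coefficients ship as
`data/vessel_table.csv` and are the single source of geometry.

Eight terminal vascular beds close the tree: paired upper-body, brain and
lung beds, one combined lower-body-and-placenta ("peripheral") bed, and a
single-resistor coronary bed at the aortic arch. Each non-coronary bed is a
three-element Windkessel: a characteristic resistance `Rc` in series with a
peripheral resistance `Rp` shunted by a compliance `Cp`. `Rc` equals the
high-frequency characteristic impedance of the feeding segment, `sqrt(L/C)`
in the lossless-line limit; a Moens–Korteweg wave-speed variant
(`ρc/(πr²)`, `c = sqrt(Eh/2ρr)`) is available for sensitivity analysis and
differs by O(10%). Venous pressure is the ground reference (0 mmHg).

The two boundary conditions are imposed volumetric inflows at the aortic
and pulmonary valves; the fetal heart itself is not modelled. The full
circuit counts 29 resistors, 21 capacitors, 14 inductors and 2 inputs.

Internal computation is CGS (cm, g, s, dyn); the reporting layer converts
with 1 mmHg = 1333.22 dyn·cm⁻² to the clinical units mmHg·s·ml⁻¹
(resistance) and ml·mmHg⁻¹ (compliance).

## State-space realization and integrator

Kirchhoff's laws yield a linear time-invariant system `dx/dt = A x + B u`.
The two valve-fed segments carry the imposed inflows identically, so their
inductor currents are inputs rather than states, and the isthmus and ductus
share their distal junction, merging two shunt capacitors into one pressure
unknown; the state vector therefore holds 12 free inductor flows, 13
capacitive node pressures and 7 bed-compliance pressures (32 states).
Valve-node pressures are reconstructed afterwards from the entry-node
pressure plus the R·Q + L·dQ/dt drop of the feeding segment (periodic
central differences for dQ/dt).

Because the system is LTI and stiff (bed time constants `Rp·Cp` range from
milliseconds to seconds), the transient is advanced with an exact
exponential discretization at the output rate (1 kHz by default): with
`Ad = exp(A·dt)` and closed-form input matrices for linearly interpolated
inputs, the step `x_{k+1} = Ad x_k + B₀u_k + B₁u_{k+1}` is exact for the
piecewise-linear input and unconditionally stable, so no step-size
restriction arises from the smallest compliances. Cycle-to-cycle
propagation uses the precomputed one-cycle transition operator
(`M = Ad^N`) and a within-cycle averaging operator, making the cost of
convergence essentially two rollouts of the sampled grid regardless of the
number of cycles. Integration starts from a zero state; the run is
converged when the maximum relative change of cycle-averaged pressure
states between consecutive cycles falls below 1e-4 (default), with a
50-cycle default budget (400 for calibration/optimization inner loops,
where extreme trial parameters stretch the Windkessel time constants).
Halving the step changes every reported index by well under 0.5%.

An independent oracle, `dc_operating_point`, solves the same circuit as a
purely resistive nodal system (inductors shorted, capacitors open; each bed
reduced to `Rc + Rp`). Cycle-averaged transient flows agree with it to
better than 0.5% across random parameter sets; this dual route is exercised
in the test suite and is deliberately kept free of shared code with the
transient path.

## Inflow boundary conditions

When traced Doppler envelopes are available they are read from two-column
`time_s,velocity_cm_s` text files and resampled onto the uniform grid.
Otherwise a synthetic ventricular-outflow envelope stands in: a single
half-sine ejection pulse `V(t) = Vpeak·sin(πt/ET)` over the ejection time
`ET`, zero in diastole, with `ET` a configurable fraction of the cardiac
cycle (default 0.40, a typical fetal systolic fraction — the clinically
measured ejection times of the study subjects are not published). Velocity
converts to flow through the valve area, `Q = V·π(d/20)²` with `d` in mm.

For the healthy control the left/right output split that the model is
validated against (46% / 54%) is imposed exactly by rescaling the two
stroke volumes while preserving the combined output, because peak
velocities and valve areas under one common pulse shape do not by
themselves reproduce the split measured from real envelopes.

What the synthetic generator does NOT emulate: ejection-time differences
between subjects, A/V-wave morphology, notching, and the envelope shape
asymmetries of sick fetuses. Consequences are quantified below
(Personalization).

## Indices

* Pulsatility index: `PI = (max − min)/|time-average|` over one cycle.
  The magnitude in the denominator matches clinical reporting — the study
  population includes a severe case whose printed isthmus PI is large and
  positive although its net isthmus flow is reversed (flow index −12.36),
  which is only consistent with the magnitude convention.
* Isthmic flow index: `IFI = (systolic + diastolic)/systolic` velocity-time
  integrals, diastolic integral signed. Systole is the imposed ejection
  window of the aortic source — the model has no valves, so the input
  ejection interval is the only internal marker.
* Percentage of reversed flow: `100·|∫w⁻|/(|∫w⁻| + ∫w⁺)` by default
  (total-referenced); a forward-referenced variant is selectable since the
  source publications do not print a formula.
* Mean arterial pressure: cycle average at the aortic-arch node.
* CCO distribution: cycle-mean bed inflows grouped as brain, upper body,
  lungs, lower body & placenta, coronary, as percent of combined mean
  inflow; plus the left/right output split. These are DC quantities —
  independent of waveform shape at fixed resistances.

## Calibration of the control model

1. All bed `Rp` are scaled by one common factor (preserving the published
   ratios) until the simulated mean arterial pressure meets the target —
   the rounded 40 mmHg for the 33.2-week control, `0.87·GA + 10.33` mmHg
   otherwise. Scalar root bracketing on [0.1, 10] (Brent).
2. The four grouped bed compliances (brain, upper, lungs, peripheral;
   left/right tied) are estimated by multistart bounded optimization of
   `J = |ΔPI_AoI|/PI_AoI + |ΔPI_CA|/PI_CA` against the measured control
   values (3.39, 2.82), searched in log-space within [1e-4, 0.1] ml·mmHg⁻¹,
   initial points at the current values plus uniform random draws, stopping
   when `J < 0.01`. The control calibration converges with
   `J ≈ 0.004–0.009`.

## Personalization

For an individual subject the pipeline (i) re-evaluates geometry at the
subject's gestational age, (ii) rescales dimensions, bed resistances and
compliances allometrically with the weight ratio `Wi/W0` (reference weight
from `log10 W = 0.2508 + 0.1458·GA − 0.0016·GA²`; default exponents 0.33,
−0.933 and 1.33 for dimensions, resistances and compliances — literature
scaling conventions, deliberately configurable), (iii) retargets the mean
pressure, and (iv) estimates six parameters: brain and peripheral
resistance scale factors (bounds [0.2, 6]) and the four grouped compliances.

Two pulsatility indices cannot identify six parameters: compliance changes
mimic resistance effects on pulsatility, so the raw problem has a
2-dimensional zero set and branch ambiguity (peripheral-driven vs
compliance-driven isthmus pulsatility). The estimation is therefore kept
constrained: the minimized objective augments J with the relative errors of
the rest of the per-subject index panel when the record carries it (IFI,
% reversed isthmus flow, PI_dAo/PI_CA) and with the deviation from the
gestational-age-appropriate mean pressure, which the procedure keeps
enforced while the resistances move; a small quadratic penalty (1e-2)
toward the scaled-baseline prior makes any residual null direction
reproducible. Because the resistance plane is the multi-basin part of the
landscape, local starts are seeded from a coarse 7×7 log-grid scan scored
on the compliance-insensitive integral observables, followed by
Nelder–Mead refinement (direction-set methods stall in the narrow curved
valleys of the PI objective). The reported `objective_value` is always the
pure two-PI J.

Identifiability, stated openly:

* On model-generated data (panel produced by the model itself under known
  fold changes, same inflows), peripheral ×3.7 and brain ÷1.7 are recovered
  to within ~1%, deterministically across seeds.
* Compliance recovery is a regularized self-consistency property: with the
  generating values among the starts the estimator returns them; recovery
  of four compliances from two PIs without regularization is structurally
  non-identifiable.
* On the real growth-restricted records driven by SYNTHETIC envelopes, the
  right-dominant inflows of the sick fetuses (left output share down to
  ~28%) already generate most of the isthmus abnormality, so the estimator
  attributes little to resistance remodeling — fold changes land near 1 and
  the expected ordering (peripheral change exceeding brain change) is not
  robustly reproduced. Forward-simulating the published fitted parameter
  sets under synthetic envelopes likewise fails to reproduce the published
  panel (for the mildest case, isthmus PI 9.5 instead of 4.25 and mean
  pressure 77 mmHg instead of ~40). Both observations carry the same
  message: the traced envelope shapes, which are not recoverable from the
  published scalars, dominate patient-specific inference. Passing
  personalization tests on synthetic data therefore demonstrate the
  estimator, not clinical validity on real Doppler traces.

## Parametric study

From the calibrated control, the peripheral resistance is multiplied by
factors up to 4 and the brain resistances divided by factors up to 4
(default 13×13 log-spaced grid; everything else, including the inflows,
held fixed). Each cell records the full index panel. Verified trends:
% reversal in the isthmus is non-decreasing in both factors across the
whole grid; isthmus PI rises along both single-factor marginals (it is
non-monotone in the grid interior where the mean isthmus flow crosses
zero and the index denominator collapses — an intrinsic property of the
clinical index, not a numerical artifact); cerebral-artery PI falls
predominantly with brain vasodilation; PI_dAo/PI_CA is ≈1.1 at baseline
and rises steeply with severity; the brain CCO share rises mainly with
brain vasodilation while the lower-body share falls mainly with peripheral
constriction.

## Numerical choices and degenerate inputs

* Output sampling 1 kHz; exact exponential stepping (no solver tolerance
  below the cycle-convergence criterion of 1e-4 on cycle-mean pressures).
* Zero inflows are a fixed point and return identically zero waveforms;
  an identically zero waveform makes % reversal undefined (raised as
  `UndefinedIndexError`), as do zero cycle means for PI and non-positive
  systolic integrals for IFI.
* Optimizer trials whose time constants prevent periodic convergence
  within 400 cycles, or whose systolic isthmus integral collapses, are
  scored with a large penalty rather than aborting the fit.
* Flow signs are positive proximal → distal; isthmus flow is positive
  toward the descending aorta.

## Problem sizes

The default test-suite and acceptance runs use 1000 samples per cycle,
3×3 sweep grids, 20 random parameter sets for the oracle-equivalence
check, 10 seeded replicates for compliance recovery, and multistart
budgets of 4–10 starts with at most 600 function evaluations per start —
sizes chosen so a complete run stays in the minutes range on a single
core while leaving every reported digit stable to well below the stated
tolerances.

## Known limitations

* 0D only: no wave propagation or spatial gradients; no venous return,
  foramen ovale or umbilical-vein circuit; one combined lower-body &
  placenta bed.
* Inflows are imposed: no heart model, no valve events, no ventricular
  interaction; right-ventricular dominance enters only through the input
  data.
* The synthetic ejection waveform is a single half-sine; all
  waveform-shape-dependent indices (PI, IFI, % reversal) are approximate
  stand-ins for values computed from traced Doppler envelopes.
* The brain CCO share of the control model computes to 13.5% against a
  published 16%: at fixed resistance ratios the share is fully determined
  by the circuit (a DC property), and neither characteristic-impedance
  convention closes the gap — reproducing 16% would require a near-zero
  series impedance on the cerebral path together with the published
  peripheral-resistance ratios. All other shares match within ±2 points.
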