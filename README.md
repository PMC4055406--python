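# fetalflow

A lumped-parameter (electrical-analog, 0D) model of the fetal arterial
circulation for studying blood-flow redistribution in intrauterine growth
restriction (IUGR).

In a fetus the aortic isthmus is the only arterial bridge between the left
heart, which perfuses the brain, and the right heart, which perfuses the
lower body and placenta through the ductus arteriosus. When placental
resistance rises and the cerebral beds dilate ("brain sparing"), diastolic
flow in the isthmus weakens and can reverse — a pattern used clinically to
stage IUGR severity. `fetalflow` models this system as an electrical
circuit: 14 arterial segments, each a series R–L branch with a shunt
capacitor (R = 8μl/πr⁴, L = ρl/πr², C = 3πr³l/2Eh, with geometry growing
linearly with gestational age and h = 0.15 r), terminated by 8 vascular
beds — paired upper-body, brain and lung three-element Windkessels
(Rc–[Rp‖Cp]), one combined lower-body & placenta bed and a coronary
resistor — driven by imposed aortic and pulmonary valve inflows and
grounded at 0 mmHg venous pressure.

The package is meant for computational physiologists and biomedical
engineers who want to ask "what does a given combination of cerebral
vasodilation and placental resistance increase do to isthmus and cerebral
Doppler indices?" — and, inversely, to estimate those resistance changes
from a subject's measured index panel.

It provides:

* **anatomy / components / network** — gestational-age-dependent geometry,
  electrical elements, and the assembled circuit with its state-space
  (LTI) realization and an independent DC resistive oracle;
* **inflow** — synthetic half-sine ejection waveforms from clinical scalars
  (heart rate, peak velocity, valve diameter), velocity-trace file I/O and
  velocity→flow conversion;
* **simulate** — stiff-safe exact-exponential integration to periodic
  steady state with named probe sites (isthmus, ductus, cerebral arteries,
  every bed, every node pressure);
* **indices** — pulsatility index, isthmic flow index, % reversed flow,
  mean arterial pressure and the distribution of combined cardiac output;
* **fit** — calibration (mean-pressure targeting and compliance
  estimation) and patient personalization (allometric scaling plus
  6-parameter constrained estimation);
* **study** — resistance-sweep engine over peripheral × brain factors;
* a thin CLI (`fetalflow simulate|calibrate|sweep|personalize|fixtures`).

See `docs/methods.md` for the model's assumptions, numerical scheme,
parameter defaults and known limitations, and `examples/` for narrative
scripts.

## Worked example

`examples/02_calibrate_control.py` calibrates the healthy 33.2-week control
model — uniform resistance scaling to the 40 mmHg mean-pressure target,
then multistart estimation of the four grouped bed compliances against the
measured pulsatility indices — and prints:

```
resistance calibration factor: 1.185
compliance fit: J = 0.0044 (converged=True, starts=1)
  cp_brain         0.0046 ml/mmHg
  cp_upper         0.0457 ml/mmHg
  cp_lungs         0.0181 ml/mmHg
  cp_peripheral    0.0123 ml/mmHg

mean arterial pressure :  40.00 mmHg
isthmus PI             :   3.38 (target 3.39)
cerebral PI            :   2.82 (target 2.82)
isthmic flow index     :   1.51
reversed isthmus flow  :   10.3 %
```

J is the summed relative error of the two pulsatility indices; a value
below 0.01 means both Doppler targets are reproduced. The isthmic flow
index above 1 and the small reversal fraction describe a healthy isthmus
with net forward diastolic flow toward the placenta.

`examples/03_resistance_sweep.py` then raises the peripheral resistance up
to four-fold while dilating the brain beds up to four-fold:

```
reversed isthmus flow (%) / brain share of CCO (%)
R_brain /R_per x            1.0           2.0           4.0
     1.0   10.3/13.5   28.8/17.9   52.4/22.3
     2.0   21.0/21.2   46.5/27.3   72.3/33.0
     4.0   37.6/29.6   67.5/37.0   86.0/43.5
```

Reversal grows along both axes — placental resistance increase and
cerebral vasodilation independently pull diastolic isthmus flow backwards
— while the brain's share of combined output responds mainly to the brain
resistance, the signature of brain sparing.

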