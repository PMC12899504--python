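# footcontact

Foot contact detection from wearable inertial sensors during high-dynamic
sports movements — sidestep cuts (COD) and sprint decelerations (DEC) —
with force-plate validation statistics and a seeded synthetic-trial
generator.

Precise timing of **initial contact (IC)** and **toe-off (TO)** is the
backbone of field-based biomechanics: stance-phase kinematics, loading
asymmetries and injury-risk metrics (e.g. around ACL-relevant cutting
maneuvers) all hinge on it. In the lab, IC/TO come from a force platform:
IC is the first frame where the vertical ground reaction force (vGRF)
exceeds 50 N, TO the first subsequent frame below it. On the field there
is no force plate — only IMUs, typically a pelvis sensor and foot sensors
sampling at 60 Hz.

This package implements three IMU-only detectors and everything needed to
validate them:

* **PVV** (pelvis vertical velocity): after a zero-phase third-order
  Butterworth low-pass at 20 Hz, IC candidates are local minima of the
  pelvis vertical velocity and TO candidates local maxima; a pair (IC, TO)
  is accepted when a descent follows the TO (velocity derivative below
  −0.1 m/s²) and the TO is the highest peak before that descent.
* **RFA** (resultant foot acceleration): on the filtered norm
  ‖(aₓ, a_y, a_z)‖ of the foot accelerometer, IC and TO are impact-like
  local maxima; an eligible TO peak must reach 30 m/s² and the pair must
  enclose a "U-shaped" valley. 
* **Hybrid**: RFA for both events; PVV as fallback when RFA finds no
  valid window; and when the foot acceleration at IC is below 60 m/s²
  (the regime where impact peaks degrade), PVV's IC replaces RFA's while
  TO stays with RFA.

All detectors report every acceptable candidate window; the longest one is
selected as the task's plant step. Agreement with the reference is
quantified by the median offset and IQR (offset = reference time −
detected time, in ms; positive = detector early), Bland–Altman mean
offset and 1.96·SD limits of agreement, a linear mixed-effects model of
the error on task/sex/leg with a per-participant random intercept, and
Pearson correlations against candidate error sources.

Because raw laboratory recordings of this kind are rarely shareable, the
`synthetic` module generates full cohorts with analytically planted
events (stance 478.3 ± 162.1 ms, contact-peak acceleration
94.6 ± 36.8 m/s², ~17.5 % low-acceleration trials), so the whole chain is
testable end to end. See `docs/methods.md` for the model details.

## Worked example

```python
import numpy as np
from footcontact import (
    CohortSpec, TrialMeta, Task, Sex, Leg, generate_trial,
    detect_grf_contact, detect_hybrid, compute_offset, EventType, Algorithm,
)

spec = CohortSpec(seed=42)
meta = TrialMeta("P01_T01", "P01", Task.COD, Sex.FEMALE, Leg.DOMINANT)
trial, truth = generate_trial(spec, meta, np.random.default_rng(42))

reference = detect_grf_contact(trial.vgrf)           # 50 N rule, 1000 Hz
result = detect_hybrid(trial.pelvis_vz, trial.foot_acc)  # IMU-only, 60 Hz

print(f"planted stance   : {truth.ic_time:.3f} -> {truth.to_time:.3f} s")
print(f"force-plate ref  : {reference.ic_time:.3f} -> {reference.to_time:.3f} s")
print(f"hybrid detection : {result.contact.ic_time:.3f} -> "
      f"{result.contact.to_time:.3f} s  (provenance {result.provenance.value})")
ic = compute_offset(reference, result.contact, EventType.IC, meta, Algorithm.HYBRID)
to = compute_offset(reference, result.contact, EventType.TO, meta, Algorithm.HYBRID)
print(f"IC offset {ic.offset_ms:+.1f} ms, TO offset {to.offset_ms:+.1f} ms")
```

prints

```
planted stance   : 1.242 -> 1.769 s
force-plate ref  : 1.242 -> 1.770 s
hybrid detection : 1.233 -> 1.767 s  (provenance RFA_BOTH)
IC offset +8.7 ms, TO offset +3.3 ms
```

The force plate recovers the planted 50 N crossings to within 1 ms; the
hybrid detector, working only from the 60 Hz IMU channels, lands within a
single IMU sample (16.7 ms) of the reference, and the positive offsets say
it fired slightly early. `provenance RFA_BOTH` records that the contact
peak was strong enough (≥ 60 m/s²) for the acceleration route alone.

## Command line

```sh
footcontact simulate --seed 1 --out cohort/          # trial CSVs + truth
footcontact detect   --in cohort/ --algorithm all    # events JSON
footcontact validate --in cohort/ --out report/      # tables, Bland-Altman
```

All thresholds (50 N, 20 Hz / order 3, −0.1 m/s², 30 m/s², 60 m/s²) live
in a JSON/TOML config and are logged with every run.

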