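# Methods

This note documents the models, parameter choices and numerical decisions
behind `footcontact`, and what the synthetic validation does and does not
establish.

## Data model

All channels of a trial share one clock: sample `k` of a signal with rate
`r` and origin `t0` sits at `t0 + k/r` seconds. Indexing is 0-based.
Events carry both their sample index (on the detecting signal's clock) and
their time in seconds on the shared clock, so a 1000 Hz force-plate event
and a 60 Hz IMU event compare directly; cross-rate index mapping uses
nearest-sample rounding with half-up midpoints. The CSV interchange format
stores one uniform time column plus channel columns; uniformity is
enforced to 1 µs.

## Force-plate reference

IC is the first sample with vGRF strictly above 50 N, TO the first
subsequent sample strictly below it; a sample exactly at the threshold
triggers neither ("exceeds"/"drops below" read literally). Two practical
amendments, both configurable:

* **Debounce** (`min_contact_s`, default 50 ms): force plates ring near
  the threshold; supra-threshold windows shorter than the debounce are
  treated as ringing and skipped. Set 0 to keep every crossing.
* **Longest window**: if several windows survive, the longest is the
  plant step, mirroring the detectors' valid-step rule (earliest on ties).
  A contact still above threshold at the end of the recording raises a
  truncated-contact error rather than returning a fabricated toe-off.

The reference thresholds the raw force signal; no pre-filtering is
applied to it.

## Detectors

Both single-signal detectors first low-pass their input with a
third-order Butterworth at 20 Hz. Filtering is **zero-phase**
(forward–backward): a causal pass of this filter at 60 Hz delays
landmarks by several samples and would bias every offset in one
direction, which is unacceptable in a timing-validation tool. The causal
mode is available for sensitivity analyses. Zero-phase filtering squares
the magnitude response (−6 dB rather than −3 dB at the cutoff), which is
irrelevant here since only landmark positions matter.

Candidate extrema are strict local extrema with a prominence floor of
`min_prominence_frac` (default 0.05) times the filtered signal's range.
The floor suppresses noise-born micro-extrema; with it set to 0 the
candidate set is exactly the strict-sign-change extrema, which is what
the exhaustive-enumeration tests use.

**PVV pairing.** For each candidate IC (local minimum, ascending order),
candidate TOs (local maxima) after it are scanned in order. A TO is
accepted when (a) the derivative of the filtered velocity (central
differences, SI units) falls below −0.1 m/s² at some sample after the TO
and before the next candidate TO — the "descent" — and (b) the TO is the
highest candidate maximum between the IC and the descent onset. The
descent search window and the comparison set in (b) are design choices:
the pattern definition bounds neither, and the next-candidate-TO bound
makes the scan deterministic and local. The first accepted TO closes the
pair; each IC contributes at most one candidate window.

**RFA pairing.** On the filtered resultant acceleration, every prominent
local maximum is a candidate for either event. For each candidate IC
peak, subsequent peaks are scanned in order: peaks below 30 m/s² are
discarded; the first peak that reaches 30 m/s² *and* encloses a U-shaped
valley with the IC peak — inter-peak minimum below `u_shape_factor`
(default 0.5) times the lower of the two peak heights — becomes the TO.
The 0.5 factor operationalizes the "U shape" of the stance phase between
the impact peaks; it is config-exposed. There is no IC-specific height
threshold: weak contact peaks are legitimate IC candidates, which is
precisely why the hybrid gate exists.

**Valid step.** All accepted pairs are candidates; the longest-duration
one is the plant step, ties broken by the earlier IC (durations within
1 ns count as tied so equal-sample windows are not separated by float
rounding). Detection failure is encoded in the result object, never
raised.

**Hybrid.** RFA drives both events. If RFA fails, PVV's window is used
(`PVV_BOTH`). If RFA succeeds but the filtered resultant acceleration at
its IC is below the 60 m/s² gate, PVV's IC replaces RFA's while TO stays
with RFA (`PVV_IC_RFA_TO`) — unless PVV failed or its IC does not precede
RFA's TO, in which case RFA's own window is kept rather than emitting an
inverted or fabricated one. The gate is read from the same filtered
signal the detector searches, so the gating quantity is exactly the
detector's own evidence.

## Agreement statistics

Offsets are `1000 × (reference time − detected time)` ms; positive means
the detector fired early. Quantiles use linear interpolation between
order statistics (the default in the major statistical ecosystems); the
rule is fixed and tested against a from-first-principles sorted-order
oracle. Limits of agreement are mean ± 1.96 sample SD (n−1); outliers are
offsets strictly outside them. Failed detections never enter offset
summaries — they are counted separately.

The error model is a linear mixed model: offset on the three binary
factors (indicator coding — task=COD, sex=male, leg=non-dominant; DEC /
female / dominant as references) with a per-participant random intercept,
fit by REML (statsmodels `MixedLM`). A mixed model has no canonical R²,
so the reported adjusted R² and overall model p come from the
fixed-effects-only OLS fit; this is a documented package convention, not
an attempt to match any particular variant.

## Synthetic cohort generator

The generator fabricates the *landmark geometry* the detectors consume,
not biomechanics. Waveforms are smooth parametric bumps (raised cosines
and Gaussians): the detection rules constrain only the landmark pattern,
so any smooth family realizing that pattern is adequate, and parametric
bumps make every planted time analytic.

* **vGRF (1000 Hz)**: a 30 ms raised-cosine ramp reaches exactly 50 N at
  the planted IC, a half-sine bump (peak 1.2–2.2 kN) carries stance, and
  a mirror ramp decays after TO — so the 50 N crossings are planted by
  construction and recovery can be asserted to 1 ms.
* **Pelvis velocity (60 Hz)**: a Gaussian dip (0.55 m/s deep) at IC and a
  Gaussian peak (0.6 m/s) at TO on a gently oscillating baseline; the
  peak's own decay provides the post-TO descent (≪ −0.1 m/s²).
* **Foot acceleration (60 Hz)**: Gaussian impact peaks (σ = 25 ms) at IC
  and TO over a ~2 m/s² baseline, split across three axes with a fixed
  unit direction so the norm reproduces the target curve exactly. TO peak
  heights are 45 ± 5 m/s² (clipped ≥ 36).

Study-scale defaults: 34 participants × 8 trials; stance durations
N(478.3, 162.1) ms clipped to [250, 900] ms (plant-step stances below
~250 ms do not occur in these tasks; the clip moves the mean by < 6 ms
and the duration-statistics test uses the analytic clipped mean as its
oracle); contact-peak heights N(94.6, 36.8) m/s². The *low-acceleration
regime* (peak < 57.8 m/s², one SD below the mean) covers a configurable
fraction of trials (default 0.175): flagged trials draw their peak below
the threshold, the rest above it, so the observed fraction equals the
requested one while the pooled distribution keeps the stated mean/SD.

**Degradation model.** In the field, low contact accelerations blur the
impact peak and degrade acceleration-based IC timing more than
velocity-based timing. The generator emulates this by displacing the
IMU-visible IC landmarks late in low-acceleration trials: the foot-
acceleration IC by 70 ms and the pelvis-velocity IC by 50 ms (both
configurable), preserving the qualitative ordering that velocity-based
detection degrades less. Degradation follows the physical regime (peak
height below `degradation_onset` = 62 m/s²) rather than the sampling
flag; the onset sits slightly above the 60 m/s² hybrid gate so that the
gate always operates inside the degraded regime — otherwise borderline
trials would be substituted without cause. The `noise_free()`
configuration zeroes noise, clock jitter and these displacements; under
it every generated trial is solvable by all three detectors to within one
IMU sample, which is the generator/detector contract the tests pin down.

**Noise.** Additive white Gaussian sensor noise, 0.008 m/s on the
velocity channel and 0.5 m/s² on each acceleration composite —
instrument-level noise, small against movement amplitudes (~1 m/s and
~100 m/s²). Larger disturbances of real data (soft-tissue artifact,
orientation drift, strap resonance) are *not* modeled; passing tests
demonstrate the algorithmic chain is correct and calibrated, not that
field recordings will reach the same accuracy.

**Distractor steps** (30 % of trials with stance ≥ 300 ms): a shorter
step after the plant, with its own valid velocity and acceleration
patterns, exercising the longest-window selection. It is placed after
the stance at offsets (0.3 d gap, 0.5 d length) chosen so that no cross
pair of extrema — e.g. the main TO peak paired with a distractor peak —
can out-last the main stance; a pre-stance distractor cannot guarantee
this when the main contact peak is weak, because its TO peak can pair
across a sub-threshold contact peak with the main TO.

**Planted factor effects** shift all IMU landmarks earlier by
`Σ β·indicator` ms, so the offset model's fixed effects are recoverable
through the full waveform → detection → offset chain.
`generate_offsets()` additionally draws offset records directly from the
error model (residual SD 8 ms by default, chosen so millisecond-scale
factor effects are resolvable at the study's sample size) for statistical
calibration at 100-seed scale, where waveform simulation would be
needlessly slow.

## Problem sizes in the validation suite

The exhaustive-enumeration equivalence sweep uses 200 random signals of
30–500 samples; ground-truth scan equivalence uses 200 random force
traces plus 40 noise-free planted stances; event recovery uses one
200-trial cohort (25 × 8, 20 % low-acceleration trials) at nominal noise;
mixed-model calibration uses 100 seeds of 34 × 8 offset draws for both
the planted-effect and the null configuration.

## Known limitations

* Waveforms are pattern-level surrogates; no soft-tissue artifact,
  drift, or orientation error, and no biomechanical coupling between
  channels.
* The hardware-trigger synchronization of plate and IMUs is assumed
  perfect (`sync_jitter_ms` exists but defaults to 0); trigger-offset
  estimation is out of scope.
* The detectors are tuned to plant-step patterns of cutting and
  deceleration tasks; continuous gait/running stride segmentation is out
  of scope.
* Quantile and adjusted-R² conventions are fixed package choices; other
  software may report slightly different values on the same offsets.
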