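# Methods

## The trigger state machine

The fall trigger is a three-phase state machine over the acceleration signal
vector magnitude (SVM), driven one sample at a time:

* `SAMPLING` — idle.  A sample with SVM strictly above `fall_threshold_g`
  (default 2.5 g) starts a capture: the peak itself is logged and the phase
  becomes `POST_PEAK` with deadline `t + post_peak_window_ms` (1000 ms).
* `POST_PEAK` — every sample is appended to the log.  The first sample whose
  timestamp strictly exceeds the deadline switches to `POST_FALL` with
  deadline `t + post_fall_quiet_ms` (1500 ms).
* `POST_FALL` — a new supra-threshold peak means the wearer is still moving
  vigorously (running, jumping): the log is cleared and capture restarts
  from that peak with a fresh 1000 ms deadline.  If instead the deadline
  expires quietly, a `FALL_EVENT` carrying the log is emitted and the
  machine returns to `SAMPLING`.

All comparisons are strict; samples exactly at a threshold or deadline do
not transition.  When a sample both exceeds the threshold and the deadline,
the re-trigger wins — a peak is positive evidence of ongoing activity,
whereas the deadline is only the absence of evidence.  The test suite pins
this semantics against an independent whole-trace reference detector that
enumerates threshold crossings and quiescence windows with index arithmetic
(property-checked on 1,000 random traces).

## Window features

The captured window (the triggering peak plus ~1 s of samples) is reduced to
13 features: SVM mean and variance; Y and Z acceleration means and standard
deviations; Y and Z angular-velocity means and standard deviations; fall
time; and one Fourier amplitude each for the acceleration and gyroscope SVM
series.  X-axis means and deviations are deliberately absent: with the X
axis vertical, its statistics are dominated by gravity and orientation
rather than by impact dynamics.

Three conventions are fixed here because they admit more than one sensible
definition:

* **Population statistics.**  Variance and standard deviation use the `1/N`
  normalisation: the window is the complete signal of interest, not a sample
  from a population, and the choice makes small-window tests exact.
* **Fall time** is the time from the first logged sample (the triggering
  peak) to the last logged sample whose SVM exceeds the trigger threshold —
  an impact-duration measure computable from exactly what the trigger logs.
  It is 0 when only the peak exceeds the threshold.
* **Fourier amplitude** is the largest non-DC magnitude of the discrete
  Fourier transform of the mean-removed series, scaled by `2/N` so that a
  pure sinusoid of amplitude A scores A.  A single amplitude-interpretable
  scalar summarises the dominant oscillation in the window.

Feature extraction is rate-free: it requires uniform sampling (each gap
within 10% of the window's median gap) but produces identical values for a
denser capture of the same signal.

## Classifier

A support-vector classifier separates FALL from ADL windows.  Features are
z-scored with the training set's per-feature mean and population standard
deviation; zero-variance features map to 0 rather than dividing by zero.
The default kernel is linear with C = 1 (reproducible, and sufficient for
the feature geometry here); a radial kernel is available through
`TrainConfig`.  The fitted model is serialised to a versioned JSON file
holding the kernel, the normalisation statistics and the decision-function
parameters, so a saved model reloads bit-stably without pickling.

## Bed-presence rules and debouncing

The rule cascade compares the three channel values with two thresholds:
"near zero" (≤ `near_zero_eps`, default 5% of the ADC full scale of 1023
counts) and "large difference" (absolute difference ≥ `large_diff_delta`,
default 40% of full scale).  The branches are evaluated in a fixed order
with first-match semantics; all other comparisons are strict, so exact ties
fall through to NOT_RECOGNIZED.  Two quirks are intentional:

* the lying-on-an-edge branches do not require the middle channel to exceed
  the far edge; the left/right symmetry property still holds and is
  property-tested over random samples;
* NOT_RECOGNIZED is transparent to debouncing — a patternless reading
  (typically a transition between postures) neither emits nor resets the
  hold timer.

A raw label becomes the stable posture after persisting strictly longer
than `min_hold_ms` (default 1000 ms), measured from the first sample of the
run of identical labels.  Mattress-only pressure is assumed to read zero;
no calibration stage exists.

## Motion detection and fusion

The standing predicate is `ax > 0.9 g` and `−0.4 g < az < 0.4 g` (strict).
The raw predicate holds on every sample while the wearer stands, so event
emission is rate-limited with a rearm period (default 2000 ms): one
MOVEMENT event when the predicate first holds, refreshed once per rearm
period while it keeps holding.  The refresh matters because fusion treats
movement as evidence with a finite lifetime.

Fusion re-evaluates its rule at every stable-position change and at every
movement event: NO_PRESENCE always raises BED_EXIT; a sitting posture
raises EXIT_INTENT iff a MOVEMENT event occurred within the last
`movement_window_ms` (default 2000 ms, half-open window `(t−w, t]`; at
equal timestamps the movement event is processed first so simultaneous
evidence counts).  At most one alarm is raised per presence episode,
re-armed when the posture changes — a caregiver needs one notification per
incident.

## The simulator

The generators encode the study conditions as defaults:

* **Falls** (forward/backward/left/right): 1 s upright, a 300 ms oriented
  impact transient whose apex magnitude is drawn from N(3.2, 0.4) g and
  clipped below at 2.6 g (the trigger threshold plus margin), then ≥ 2.6 s
  of quiescent lying in the fall-type's orientation.  The apex sample is
  pinned exactly to the drawn magnitude.  Orientation and rotation axis
  encode the fall type (lateral falls differ in the sign of ay).
* **ADLs**: a *hit* or *pull* is a sharp supra-threshold spike on the strip
  axis with no orientation change; a *jump* repeats sub-threshold peaks
  (clipped at 2.3 g); *run and stop* places supra-threshold footfalls every
  700 ms — inside the 2.5 s cancellation horizon, so the trigger keeps
  resetting until the final stop; *sit* is a moderate backward transient
  into a reclined orientation, deliberately overlapping the backward-fall
  signature (the confusable pair in the live batteries; the held-out test
  asserts backward falls are the most-confused fall type).
* **Bed exits**: a six-phase acceleration profile (lying, lying→sitting,
  sitting, sitting→standing, standing, walking) following the observed
  trajectory — ax near 0 and az near 1 while lying, reversing to ax ≈ 0.95
  with az within ±0.4 when upright — synchronised with a pressure walk
  lying-middle → lying-edge → sitting-edge → no-presence, each posture held
  ≥ 2 s.
* **Pressure patterns**: per-posture channel levels (lying middle
  (300, 700, 250); lying left (600, 800, 50); sitting left (900, 300, 0);
  mirrored on the right; all ≈ 0 for no presence) chosen to satisfy their
  rule-cascade branch with margins far above the channel noise
  (σ = 8 counts); linear 400 ms cross-fades join the holds.  `SimConfig`
  validates at construction that every configured level classifies as its
  intended posture and that 3σ of noise stays inside the near-zero band.
* **Rolling**: side–supine–side orientation cycles with ax bounded far
  below the standing threshold, for the motion detector's false-positive
  battery.

Waveform shapes (half-sine transients, logistic cross-fades) are the
simplest forms meeting these constraints; no published waveform exists to
digitise.  What the simulator does **not** model: biomechanical variability
across subjects, sensor drift and saturation, the hardware asymmetry in
which one edge strip read systematically low during the live posture
battery, and transition dynamics richer than a cross-fade.  Passing the
simulation-level suites therefore demonstrates the *logic* of the detectors
(trigger semantics, rule margins, fusion timing), not field performance on
real signals.

## Evaluation conventions

Accuracy is `(TP+TN)/total`.  Multi-class metrics reduce one-vs-rest per
class and macro-average with the unweighted arithmetic mean.  Metrics with
zero denominators raise rather than return 0.  Report output rounds
half-up to two decimals; the two-stage exit-intention chain multiplies the
stage metrics at that two-decimal precision, matching how the chain's
published figure was formed.  The bundled reference counts reproduce the
published battery metrics to two decimals, with two recorded exceptions
that are arithmetic slips in the source tables (a lying-right sensitivity
printed as 90.09 where the matrix gives 10/11 = 90.91, and a combined
accuracy printed as 96.60 where the product of its factors is 92.60); the
package reports the recomputed values.

## Problem sizes

The test suite and acceptance script run entirely on synthetic data at
desk scale: 1,000 random traces for the trigger-equivalence property, 10
seeded traces per fall type, 40 simulated bed exits (20 per side) for the
standing-phase detection rate, 10 rolling trials for the false-positive
check, and a 9-activity × 10-repetition corpus for classifier training.
These sizes were chosen to make every property tight while keeping a full
run in seconds.

## Known limitations

* The trigger thresholds and the rule-cascade structure are fixed by
  design, not learned; the package inherits their blind spots (e.g. falls
  with peak SVM below 2.5 g are invisible by construction).
* The pressure thresholds (5% / 40% of full scale) are package defaults:
  the source system never published its ADC scale or predicate constants,
  only the qualitative patterns the defaults reproduce.
* Event timestamps are integer milliseconds from stream start; cross-device
  clock synchronisation is out of scope, and the in-process event bus
  replaces all network transport with an ordered, lossless contract.
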