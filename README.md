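# bedwatch

Bedtime fall **detection** and fall **prevention** for older adults, as pure
software: the complete signal-processing chain of a monitoring system built
from a waist-worn inertial measurement unit (IMU) and three pressure strips
under the mattress, together with a seeded simulator so that every detector
can be exercised and evaluated without hardware.

Night-time bed exits are among the riskiest moments for people with cognitive
impairment or reduced mobility.  The package addresses both sides of the
problem: detecting a fall that has happened (so help arrives quickly) and
recognising the *intention* to exit the bed (so a caregiver can intervene
before a fall).

## What the package computes

**Fall detection.**  With the X axis pointing up, the acceleration signal
vector magnitude is

    SVM = sqrt(Ax² + Ay² + Az²)        [g]

A three-phase trigger state machine watches the stream: a peak with
SVM > 2.5 g opens a 1 s capture window (`POST_PEAK`); a 1.5 s quiescence
check follows (`POST_FALL`) during which a new peak cancels the capture
(running, jumping) while silence confirms it and emits a `FALL_EVENT`
carrying the window.  The window is summarised into 13 features (SVM mean
and variance, Y/Z acceleration and angular-velocity means and standard
deviations, fall time, and the dominant Fourier amplitudes of the
acceleration and gyroscope SVM series), z-scored, and classified as
FALL vs ADL (activity of daily living) by a support-vector classifier.
Only a confirmed FALL raises the caregiver alarm.

**Bed presence.**  Each (left, middle, right) pressure reading is mapped to
one of six postures (no presence, sitting/lying on either edge, lying in the
middle) by a fixed rule cascade on channel comparisons, then debounced: a
raw label must persist for more than one second to become the stable
posture.

**Motion and fusion.**  A sample with ax > 0.9 g and |az| < 0.4 g indicates
the wearer has stood up.  The `ActivityDetector` fuses both streams:
`NO_PRESENCE` raises a BED_EXIT alarm; sitting on an edge with concurrent
movement raises an EXIT_INTENT alarm.

**Evaluation.**  `bedwatch.evaluation` implements accuracy, sensitivity and
specificity, one-vs-rest reduction with macro averaging for the six-posture
confusion matrix, the prevalence decomposition
`Acc = Se·Prev + Sp·(1−Prev)`, and the independent-stage product used for
the two-stage exit-intention chain.  `bedwatch.published` carries the raw
trial counts of the original validation batteries so every reported
percentage is recomputed, never stored.

## Worked example

Simulate a bed exit from the left side and run the prevention chain over the
two generated streams:

```sh
$ bedwatch simulate bed-exit --seed 7 --out demo
wrote demo/imu.csv and demo/pressure.csv
$ bedwatch monitor --pressure demo/pressure.csv --imu demo/imu.csv --out demo/alarms.jsonl
ALARM EXIT_INTENT at t=7040 ms
ALARM BED_EXIT at t=8400 ms
2 alarms -> demo/alarms.jsonl
```

The pressure stream walks lying-middle → lying-left → sitting-left →
no-presence.  Sitting becomes the stable posture after its one-second
debounce; the first MOVEMENT event fires at 7040 ms, during the
sitting-to-standing transition of the acceleration profile, and pairs with
the sitting posture into the EXIT_INTENT alarm.  When the pressure channels
drop to zero and hold for a second, the BED_EXIT alarm follows at 8400 ms.

The same workflow covers falls:

```sh
bedwatch train --synthetic-reps 10 --seed 0 --out model.json
bedwatch simulate fall --type forward --seed 3 --out fall
bedwatch detect --imu fall/imu.csv --model model.json --out fall/events.jsonl
```

which emits one `FALL_EVENT` (the trigger) followed by one `ALARM` with
reason `FALL` (the classifier's confirmation).

`bedwatch reproduce-tables` prints the full metric tables of the validation
batteries — fall detection (accuracy 93.51%, sensitivity 92.05%, specificity
95.45% on the aggregated exercise battery), the per-posture bed-presence
metrics with their macro means, the bed-exit motion phases, and the combined
exit-intention chain — all recomputed from the bundled raw counts.

## Layout

| module                    | role                                               |
| ------------------------- | -------------------------------------------------- |
| `bedwatch.sensors`        | domain types, CSV/JSON-lines I/O, event bus        |
| `bedwatch.fall_detector`  | trigger state machine, features, SVC classifier    |
| `bedwatch.bed_presence`   | pressure rule cascade and debouncing               |
| `bedwatch.motion_detector`| standing/walking threshold detector                |
| `bedwatch.activity_fusion`| presence + movement → alarms                       |
| `bedwatch.simulator`      | seeded generators for every input signal           |
| `bedwatch.evaluation`     | confusion matrices and metric formulas             |
| `bedwatch.published`      | raw trial counts of the validation batteries       |
| `bedwatch.cli`            | `bedwatch` command-line entry point                |

See `docs/methods.md` for the modelling decisions, parameter defaults and
known limitations.
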