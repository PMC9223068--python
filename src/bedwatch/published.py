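"""Reference trial counts from the original validation campaigns.

These constants record the raw outcomes of the live test batteries the
system's published performance figures were computed from: the per-exercise
fall/ADL confusion counts (11 subjects, seven exercises performed twice),
the six-posture bed-presence confusion matrix (11 subjects walking through
every posture), and the phase-wise sensitivities of the bed-exit motion
battery (40 exits, 20 per side, with a 40-trial rolling battery supplying
the negatives).  ``bedwatch.evaluation`` and the ``reproduce-tables`` CLI
command regenerate every derived metric from these counts at run time; no
percentage is stored here.
"""

from __future__ import annotations

from .evaluation import ConfusionCounts, MultiClassConfusion

__all__ = [
    "FALL_TEST_COUNTS",
    "aggregate_fall_counts",
    "BED_POSITION_LABELS",
    "BED_POSITION_CONFUSION",
    "MOTION_PHASES",
    "MOTION_PHASE_COUNTS",
    "MOTION_PREVALENCE",
    "SITTING_CLASSES",
]

#: per-exercise fall-detector outcomes (positives are falls)
FALL_TEST_COUNTS: dict[str, ConfusionCounts] = {
    "backward_fall": ConfusionCounts(tp=17, tn=0, fp=0, fn=5),
    "forward_fall": ConfusionCounts(tp=22, tn=0, fp=0, fn=0),
    "left_fall": ConfusionCounts(tp=21, tn=0, fp=0, fn=1),
    "right_fall": ConfusionCounts(tp=21, tn=0, fp=0, fn=1),
    "run": ConfusionCounts(tp=0, tn=20, fp=2, fn=0),
    "jump": ConfusionCounts(tp=0, tn=22, fp=0, fn=0),
    "sit": ConfusionCounts(tp=0, tn=21, fp=1, fn=0),
}


def aggregate_fall_counts() -> ConfusionCounts:
    """Sum the per-exercise counts into the overall binary confusion."""
    total = ConfusionCounts(0, 0, 0, 0)
    for counts in FALL_TEST_COUNTS.values():
        total = total + counts
    return total


BED_POSITION_LABELS: tuple[str, ...] = (
    "no_presence",
    "sitting_right",
    "lying_middle",
    "lying_right",
    "lying_left",
    "sitting_left",
)

#: six-posture confusion matrix, entry [predicted][actual], 11 trials per class
BED_POSITION_CONFUSION = MultiClassConfusion(
    labels=BED_POSITION_LABELS,
    matrix=(
        (11, 0, 0, 0, 0, 0),
        (0, 11, 0, 0, 0, 0),
        (0, 0, 11, 1, 0, 0),
        (0, 0, 0, 10, 0, 0),
        (0, 0, 0, 0, 11, 5),
        (0, 0, 0, 0, 0, 6),
    ),
)

SITTING_CLASSES: tuple[str, str] = ("sitting_right", "sitting_left")

MOTION_PHASES: tuple[str, ...] = ("lying_sitting", "sitting_standing", "standing_walking")

#: bed-exit motion battery: detections out of 40 exits per phase, and the
#: 40-trial rolling battery with zero false positives as the negative side
MOTION_PHASE_COUNTS: dict[str, ConfusionCounts] = {
    "lying_sitting": ConfusionCounts(tp=37, tn=40, fp=0, fn=3),
    "sitting_standing": ConfusionCounts(tp=40, tn=40, fp=0, fn=0),
    "standing_walking": ConfusionCounts(tp=40, tn=40, fp=0, fn=0),
}

#: positives / (positives + negatives) of the motion battery: 40 / (40 + 40)
MOTION_PREVALENCE: float = 0.5
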