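"""Confusion-matrix tabulation and the detector performance metrics.

All percentage metrics follow the standard definitions

    accuracy    = 100 * (TP + TN) / (TP + TN + FP + FN)
    sensitivity = 100 * TP / (TP + FN)
    specificity = 100 * TN / (TN + FP)

plus two derived forms used to assess the prevention chain: the
prevalence decomposition ``accuracy = sensitivity * prevalence +
specificity * (1 - prevalence)`` for test batteries with a known
positive/negative split, and the independent-stage combination (elementwise
product of stage metrics as fractions) for a pipeline whose stages must both
succeed.  Multi-class confusion matrices are reduced one-vs-rest per class
and macro-averaged with the unweighted arithmetic mean.

A metric whose denominator is zero raises ``MetricUndefinedError`` instead of
silently returning 0, since silent zeros would corrupt macro means.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "MetricUndefinedError",
    "ConfusionCounts",
    "MultiClassConfusion",
    "binary_metrics",
    "per_class_metrics",
    "prevalence_accuracy",
    "combine_independent",
    "evaluate_trials",
    "round_half_up",
]

METRIC_NAMES = ("accuracy", "sensitivity", "specificity")


class MetricUndefinedError(ZeroDivisionError):
    """Raised when a requested metric has a zero denominator."""


def round_half_up(value: float, digits: int = 2) -> float:
    """Half-up decimal rounding for report output (0.125 -> 0.13 at 2 digits)."""
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.tn + other.tn, self.fp + other.fp, self.fn + other.fn
        )


def binary_metrics(c: ConfusionCounts) -> dict[str, float]:
    """Accuracy, sensitivity and specificity in percent."""
    if c.total == 0:
        raise MetricUndefinedError("accuracy undefined: no trials")
    if c.tp + c.fn == 0:
        raise MetricUndefinedError("sensitivity undefined: no positive trials (tp+fn=0)")
    if c.tn + c.fp == 0:
        raise MetricUndefinedError("specificity undefined: no negative trials (tn+fp=0)")
    return {
        "accuracy": 100.0 * (c.tp + c.tn) / c.total,
        "sensitivity": 100.0 * c.tp / (c.tp + c.fn),
        "specificity": 100.0 * c.tn / (c.tn + c.fp),
    }


@dataclass(frozen=True)
class MultiClassConfusion:
    """Confusion matrix with entry [predicted][actual]."""

    labels: tuple[str, ...]
    matrix: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        k = len(self.labels)
        if len(self.matrix) != k or any(len(row) != k for row in self.matrix):
            raise ValueError(f"matrix must be {k}x{k} to match the labels")
        if any(v < 0 for row in self.matrix for v in row):
            raise ValueError("matrix entries must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array(self.matrix, dtype=int)

    def one_vs_rest(self, label: str) -> ConfusionCounts:
        """Reduce to binary counts treating ``label`` as the positive class."""
        i = self.labels.index(label)
        m = self.as_array()
        tp = int(m[i, i])
        fp = int(m[i, :].sum() - tp)  # predicted as label, actually another class
        fn = int(m[:, i].sum() - tp)
        tn = int(m.sum() - tp - fp - fn)
        return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def per_class_metrics(m: MultiClassConfusion) -> dict:
    """One-vs-rest metrics per class plus their unweighted macro means."""
    per_class: dict[str, dict[str, float]] = {}
    for label in m.labels:
        counts = m.one_vs_rest(label)
        if counts.tp + counts.fn == 0:
            raise MetricUndefinedError(f"class {label!r} has no actual trials")
        per_class[label] = binary_metrics(counts)
    macro = {
        name: float(np.mean([per_class[label][name] for label in m.labels]))
        for name in METRIC_NAMES
    }
    return {"per_class": per_class, "macro": macro}


def _check_fraction(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be a fraction in [0, 1], got {value}")


def prevalence_accuracy(sensitivity: float, specificity: float, prevalence: float) -> float:
    """Accuracy (percent) from sensitivity/specificity fractions and prevalence."""
    _check_fraction("sensitivity", sensitivity)
    _check_fraction("specificity", specificity)
    _check_fraction("prevalence", prevalence)
    return 100.0 * (sensitivity * prevalence + specificity * (1.0 - prevalence))


def combine_independent(
    stage_a: Mapping[str, float], stage_b: Mapping[str, float]
) -> dict[str, float]:
    """Metrics (percent) of two independent stages that must both succeed."""
    out = {}
    for name in stage_a.keys() & stage_b.keys():
        _check_fraction(f"stage_a[{name}]", stage_a[name])
        _check_fraction(f"stage_b[{name}]", stage_b[name])
        out[name] = 100.0 * stage_a[name] * stage_b[name]
    if not out:
        raise ValueError("stages share no metric names")
    return out


def evaluate_trials(
    predictions: Mapping[str, str],
    ground_truth: Mapping[str, str],
    labels: Sequence[str] | None = None,
    positive: str = "FALL",
) -> ConfusionCounts | MultiClassConfusion:
    """Tabulate predicted vs actual labels over matching trial identifiers.

    With ``labels`` given, builds a multi-class confusion matrix over that
    class order; otherwise reduces to binary counts with ``positive`` as the
    positive class.
    """
    missing = set(ground_truth) - set(predictions)
    extra = set(predictions) - set(ground_truth)
    if missing or extra:
        raise ValueError(
            f"trial identifiers do not match: missing={sorted(missing)[:5]} "
            f"extra={sorted(extra)[:5]}"
        )
    if labels is not None:
        labels = tuple(labels)
        index = {lab: i for i, lab in enumerate(labels)}
        m = np.zeros((len(labels), len(labels)), dtype=int)
        for trial, actual in ground_truth.items():
            predicted = predictions[trial]
            if actual not in index or predicted not in index:
                raise ValueError(f"trial {trial!r} has a label outside {labels}")
            m[index[predicted], index[actual]] += 1
        return MultiClassConfusion(labels=labels, matrix=tuple(tuple(int(v) for v in row) for row in m))
    tp = tn = fp = fn = 0
    for trial, actual in ground_truth.items():
        predicted = predictions[trial]
        if actual == positive:
            tp, fn = (tp + 1, fn) if predicted == positive else (tp, fn + 1)
        else:
            fp, tn = (fp + 1, tn) if predicted == positive else (fp, tn + 1)
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)
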