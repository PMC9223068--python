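"""Fall detection: trigger state machine, window features, and the classifier.

The wearable firmware runs a threshold state machine over the acceleration
signal vector magnitude (SVM).  A peak above ``fall_threshold_g`` (2.5 g by
default) starts a one-second capture window (POST_PEAK).  After the window a
1.5 s quiescence check follows (POST_FALL): a new peak during that check means
the wearer is still moving vigorously (e.g. running), so the captured window
is discarded and capture restarts; an uneventful check means the movement
ended abruptly and a FALL_EVENT carrying the window is emitted.

The gateway then summarises the captured window into 13 features, z-scores
them with statistics learned on the training set, and a maximum-margin
(support-vector) classifier decides between FALL and ADL (activity of daily
living).  Only a confirmed FALL raises the caregiver alarm.

Window statistics are population statistics (the window is the complete
signal of interest, not a sample).  The Fourier features are the largest
non-DC discrete-Fourier magnitude of the mean-removed SVM series, scaled by
2/N so a pure sinusoid of amplitude A scores A.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from sklearn.svm import SVC

from .sensors import AlarmReason, Event, EventKind, ImuSample, svm

__all__ = [
    "DetectorConfig",
    "Phase",
    "DetectorState",
    "step",
    "detect_fall_events",
    "capture_window",
    "FEATURE_NAMES",
    "FeatureVector",
    "extract_features",
    "normalize",
    "denormalize",
    "FALL_ACTIVITIES",
    "ADL_ACTIVITIES",
    "LabeledWindow",
    "TrainConfig",
    "TrainedModel",
    "train",
    "classify",
    "gateway_process",
    "run_fall_pipeline",
]

FALL_ACTIVITIES = frozenset({"forward_fall", "backward_fall", "left_fall", "right_fall"})
ADL_ACTIVITIES = frozenset({"hit", "jump", "run_stop", "sit", "pull"})

MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class DetectorConfig:
    """Thresholds and deadlines of the trigger state machine."""

    fall_threshold_g: float = 2.5
    post_peak_window_ms: int = 1000
    post_fall_quiet_ms: int = 1500


class Phase(Enum):
    SAMPLING = "SAMPLING"
    POST_PEAK = "POST_PEAK"
    POST_FALL = "POST_FALL"


@dataclass(frozen=True)
class DetectorState:
    """Phase, current deadline, and the capture log of the state machine."""

    phase: Phase = Phase.SAMPLING
    time_reference_ms: int | None = None
    log: tuple[ImuSample, ...] = ()

    @classmethod
    def initial(cls) -> "DetectorState":
        return cls()


def step(
    state: DetectorState,
    sample: ImuSample,
    config: DetectorConfig = DetectorConfig(),
    source: str = "imu",
) -> tuple[DetectorState, Event | None]:
    """Advance the trigger state machine by one sample.

    Returns the successor state and, when a quiescence check completes, the
    FALL_EVENT carrying the captured window.  All comparisons are strict:
    a sample exactly at the threshold or exactly at a deadline does not
    transition.
    """
    if state.log and sample.t_ms <= state.log[-1].t_ms:
        raise ValueError(
            f"out-of-order sample at t_ms={sample.t_ms} (log ends at {state.log[-1].t_ms})"
        )
    magnitude = svm(sample.ax, sample.ay, sample.az)

    if state.phase is Phase.SAMPLING:
        if magnitude > config.fall_threshold_g:
            return (
                DetectorState(
                    phase=Phase.POST_PEAK,
                    time_reference_ms=sample.t_ms + config.post_peak_window_ms,
                    log=(sample,),
                ),
                None,
            )
        return state, None

    if state.phase is Phase.POST_PEAK:
        new_log = state.log + (sample,)
        if sample.t_ms > state.time_reference_ms:
            return (
                DetectorState(
                    phase=Phase.POST_FALL,
                    time_reference_ms=sample.t_ms + config.post_fall_quiet_ms,
                    log=new_log,
                ),
                None,
            )
        return replace(state, log=new_log), None

    # POST_FALL: a new peak cancels the pending fall and restarts capture;
    # otherwise an expired quiescence deadline confirms the fall.
    if magnitude > config.fall_threshold_g:
        return (
            DetectorState(
                phase=Phase.POST_PEAK,
                time_reference_ms=sample.t_ms + config.post_peak_window_ms,
                log=(sample,),
            ),
            None,
        )
    if sample.t_ms > state.time_reference_ms:
        event = Event(
            t_ms=sample.t_ms,
            kind=EventKind.FALL_EVENT,
            source=source,
            window=state.log,
        )
        return DetectorState.initial(), event
    return state, None


def detect_fall_events(
    samples: Iterable[ImuSample],
    config: DetectorConfig = DetectorConfig(),
    source: str = "imu",
) -> list[Event]:
    """Replay the state machine over a whole trace, collecting FALL_EVENTs."""
    state = DetectorState.initial()
    events: list[Event] = []
    for sample in samples:
        state, event = step(state, sample, config, source)
        if event is not None:
            events.append(event)
    return events


def capture_window(
    samples: Sequence[ImuSample],
    config: DetectorConfig = DetectorConfig(),
) -> tuple[ImuSample, ...]:
    """Reduce a whole trace to its captured window.

    Returns the trigger state machine's log when the trace fires it;
    otherwise (e.g. a jump whose peaks stay below threshold) the window of
    ``post_peak_window_ms`` starting at the magnitude peak.
    """
    if len(samples) == 0:
        raise ValueError("empty trace")
    events = detect_fall_events(samples, config)
    if events:
        return events[0].window
    mags = [svm(s.ax, s.ay, s.az) for s in samples]
    if len(samples) > 1:
        dt = (samples[-1].t_ms - samples[0].t_ms) / (len(samples) - 1)
        win_n = min(len(samples), round(config.post_peak_window_ms / dt) + 1)
    else:
        win_n = 1
    i = int(np.argmax(mags))
    i = max(0, min(i, len(samples) - win_n))
    return tuple(samples[i : i + win_n])


FEATURE_NAMES: tuple[str, ...] = (
    "svm_mean",
    "svm_var",
    "acc_y_mean",
    "acc_z_mean",
    "gyr_y_mean",
    "gyr_z_mean",
    "fall_time_ms",
    "acc_y_std",
    "acc_z_std",
    "gyr_y_std",
    "gyr_z_std",
    "fourier_acc_svm",
    "fourier_gyr_svm",
)


@dataclass(frozen=True)
class FeatureVector:
    """The 13 movement features summarising a captured window."""

    svm_mean: float
    svm_var: float
    acc_y_mean: float
    acc_z_mean: float
    gyr_y_mean: float
    gyr_z_mean: float
    fall_time_ms: float
    acc_y_std: float
    acc_z_std: float
    gyr_y_std: float
    gyr_z_std: float
    fourier_acc_svm: float
    fourier_gyr_svm: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values: Sequence[float]) -> "FeatureVector":
        if len(values) != len(FEATURE_NAMES):
            raise ValueError(f"expected {len(FEATURE_NAMES)} features, got {len(values)}")
        return cls(**{n: float(v) for n, v in zip(FEATURE_NAMES, values)})


def _dominant_fourier_amplitude(series: np.ndarray) -> float:
    """Largest non-DC DFT magnitude of the mean-removed series, scaled 2/N."""
    n = len(series)
    if n < 2:
        return 0.0
    spectrum = np.fft.rfft(series - series.mean())
    mags = 2.0 * np.abs(spectrum[1:]) / n
    return float(mags.max()) if mags.size else 0.0


def extract_features(
    window: Sequence[ImuSample],
    rate_hz: float = 50.0,
    fall_threshold_g: float = 2.5,
) -> FeatureVector:
    """Summarise a captured window into the 13-feature vector.

    The window must be non-empty and uniformly sampled: every inter-sample
    gap within 10% of the window's median gap (the statistics themselves are
    rate-free, so a denser capture of the same signal scores identically).
    X-axis means/deviations are intentionally not part of the feature set.
    """
    if len(window) == 0:
        raise ValueError("empty window")
    t = np.array([s.t_ms for s in window], dtype=float)
    if len(window) > 1:
        dt = np.diff(t)
        nominal = float(np.median(dt))
        if np.any(np.abs(dt - nominal) > 0.1 * nominal):
            raise ValueError(
                f"non-uniform sampling: spacing deviates more than 10% from {nominal:.3f} ms"
            )

    acc = np.array([[s.ax, s.ay, s.az] for s in window], dtype=float)
    gyr = np.array([[s.gx, s.gy, s.gz] for s in window], dtype=float)
    acc_svm = np.linalg.norm(acc, axis=1)
    gyr_svm = np.linalg.norm(gyr, axis=1)

    supra = np.nonzero(acc_svm > fall_threshold_g)[0]
    # impact duration: first logged sample (the triggering peak) to the last
    # supra-threshold sample in the window; 0 when at most the peak exceeds
    fall_time = float(t[supra[-1]] - t[0]) if supra.size else 0.0

    return FeatureVector(
        svm_mean=float(acc_svm.mean()),
        svm_var=float(acc_svm.var()),
        acc_y_mean=float(acc[:, 1].mean()),
        acc_z_mean=float(acc[:, 2].mean()),
        gyr_y_mean=float(gyr[:, 1].mean()),
        gyr_z_mean=float(gyr[:, 2].mean()),
        fall_time_ms=fall_time,
        acc_y_std=float(acc[:, 1].std()),
        acc_z_std=float(acc[:, 2].std()),
        gyr_y_std=float(gyr[:, 1].std()),
        gyr_z_std=float(gyr[:, 2].std()),
        fourier_acc_svm=_dominant_fourier_amplitude(acc_svm),
        fourier_gyr_svm=_dominant_fourier_amplitude(gyr_svm),
    )


def normalize(features: FeatureVector | np.ndarray, means: np.ndarray, stds: np.ndarray) -> np.ndarray:
    """Z-score a feature vector; zero-variance features map to 0."""
    x = features.as_array() if isinstance(features, FeatureVector) else np.asarray(features, float)
    means = np.asarray(means, dtype=float)
    stds = np.asarray(stds, dtype=float)
    if x.shape != means.shape or x.shape != stds.shape:
        raise ValueError("feature/statistics dimension mismatch")
    out = np.zeros_like(x)
    nz = stds > 0
    out[nz] = (x[nz] - means[nz]) / stds[nz]
    return out


def denormalize(z: np.ndarray, means: np.ndarray, stds: np.ndarray) -> np.ndarray:
    """Inverse of :func:`normalize` (zero-variance features recover the mean)."""
    z = np.asarray(z, dtype=float)
    means = np.asarray(means, dtype=float)
    stds = np.asarray(stds, dtype=float)
    if z.shape != means.shape or z.shape != stds.shape:
        raise ValueError("feature/statistics dimension mismatch")
    return means + z * stds


@dataclass(frozen=True)
class LabeledWindow:
    """A captured window with its ground-truth label and source activity."""

    window: tuple[ImuSample, ...]
    label: str  # "FALL" | "ADL"
    activity: str

    def __post_init__(self) -> None:
        if self.label not in ("FALL", "ADL"):
            raise ValueError(f"label must be FALL or ADL, got {self.label!r}")
        if self.activity in FALL_ACTIVITIES and self.label != "FALL":
            raise ValueError(f"activity {self.activity!r} must be labeled FALL")
        if self.activity in ADL_ACTIVITIES and self.label != "ADL":
            raise ValueError(f"activity {self.activity!r} must be labeled ADL")


@dataclass(frozen=True)
class TrainConfig:
    kernel: str = "linear"  # "linear" | "radial"
    C: float = 1.0
    rate_hz: float = 50.0
    fall_threshold_g: float = 2.5

    def __post_init__(self) -> None:
        if self.kernel not in ("linear", "radial"):
            raise ValueError(f"kernel must be 'linear' or 'radial', got {self.kernel!r}")


@dataclass(frozen=True)
class TrainedModel:
    """Immutable, JSON-serializable fall/ADL classifier.

    Holds the per-feature normalization statistics learned from the training
    set and the fitted maximum-margin decision function.  For the linear
    kernel the weight vector and intercept suffice; the radial kernel stores
    support vectors and dual coefficients.  Prediction is FALL when the
    decision function is positive.
    """

    kernel: str
    C: float
    rate_hz: float
    fall_threshold_g: float
    feature_means: tuple[float, ...]
    feature_stds: tuple[float, ...]
    weights: tuple[float, ...] | None = None
    intercept: float = 0.0
    support_vectors: tuple[tuple[float, ...], ...] | None = None
    dual_coef: tuple[float, ...] | None = None
    gamma: float | None = None

    def decision_value(self, z: np.ndarray) -> float:
        if self.kernel == "linear":
            return float(np.dot(z, np.array(self.weights)) + self.intercept)
        sv = np.array(self.support_vectors, dtype=float)
        dc = np.array(self.dual_coef, dtype=float)
        k = np.exp(-self.gamma * np.sum((sv - z) ** 2, axis=1))
        return float(np.dot(dc, k) + self.intercept)

    def to_json(self) -> str:
        payload = {
            "format_version": MODEL_FORMAT_VERSION,
            "kernel": self.kernel,
            "C": self.C,
            "rate_hz": self.rate_hz,
            "fall_threshold_g": self.fall_threshold_g,
            "feature_names": list(FEATURE_NAMES),
            "feature_means": list(self.feature_means),
            "feature_stds": list(self.feature_stds),
            "labels": {"negative": "ADL", "positive": "FALL"},
            "weights": list(self.weights) if self.weights is not None else None,
            "intercept": self.intercept,
            "support_vectors": [list(v) for v in self.support_vectors]
            if self.support_vectors is not None
            else None,
            "dual_coef": list(self.dual_coef) if self.dual_coef is not None else None,
            "gamma": self.gamma,
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "TrainedModel":
        d = json.loads(text)
        if d.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError(f"unsupported model format version {d.get('format_version')!r}")
        return cls(
            kernel=d["kernel"],
            C=d["C"],
            rate_hz=d["rate_hz"],
            fall_threshold_g=d["fall_threshold_g"],
            feature_means=tuple(d["feature_means"]),
            feature_stds=tuple(d["feature_stds"]),
            weights=tuple(d["weights"]) if d["weights"] is not None else None,
            intercept=d["intercept"],
            support_vectors=tuple(tuple(v) for v in d["support_vectors"])
            if d["support_vectors"] is not None
            else None,
            dual_coef=tuple(d["dual_coef"]) if d["dual_coef"] is not None else None,
            gamma=d["gamma"],
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json(), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        return cls.from_json(Path(path).read_text(encoding="utf-8"))


def train(
    dataset: Sequence[LabeledWindow],
    config: TrainConfig = TrainConfig(),
    seed: int = 0,
) -> TrainedModel:
    """Fit the fall/ADL classifier on labeled windows.

    Features are extracted per window, normalization statistics are computed
    from the training set only (population std; zero-variance features pass
    through as 0), and a support-vector classifier is fitted.  Deterministic
    for a given dataset, config and seed.
    """
    labels = {w.label for w in dataset}
    if labels != {"FALL", "ADL"}:
        raise ValueError(f"training set must contain both FALL and ADL windows, got {labels}")

    X = np.array(
        [
            extract_features(w.window, config.rate_hz, config.fall_threshold_g).as_array()
            for w in dataset
        ]
    )
    y = np.array([1 if w.label == "FALL" else 0 for w in dataset])
    means = X.mean(axis=0)
    stds = X.std(axis=0)
    Z = np.array([normalize(x, means, stds) for x in X])

    sk_kernel = "linear" if config.kernel == "linear" else "rbf"
    clf = SVC(kernel=sk_kernel, C=config.C, random_state=seed)
    clf.fit(Z, y)

    common = dict(
        kernel=config.kernel,
        C=config.C,
        rate_hz=config.rate_hz,
        fall_threshold_g=config.fall_threshold_g,
        feature_means=tuple(float(v) for v in means),
        feature_stds=tuple(float(v) for v in stds),
        intercept=float(clf.intercept_[0]),
    )
    if config.kernel == "linear":
        return TrainedModel(weights=tuple(float(v) for v in clf.coef_[0]), **common)
    return TrainedModel(
        support_vectors=tuple(tuple(float(v) for v in row) for row in clf.support_vectors_),
        dual_coef=tuple(float(v) for v in clf.dual_coef_[0]),
        gamma=float(clf._gamma),
        **common,
    )


def classify(model: TrainedModel, window: Sequence[ImuSample]) -> str:
    """Classify a captured window as "FALL" or "ADL" with a trained model."""
    features = extract_features(window, model.rate_hz, model.fall_threshold_g)
    z = normalize(features, np.array(model.feature_means), np.array(model.feature_stds))
    return "FALL" if model.decision_value(z) > 0 else "ADL"


def gateway_process(event: Event, model: TrainedModel) -> Event | None:
    """Gateway reaction to a FALL_EVENT: classify its window, alarm on FALL."""
    if event.kind is not EventKind.FALL_EVENT:
        raise ValueError(f"expected a FALL_EVENT, got {event.kind.value}")
    if not event.window:
        raise ValueError("FALL_EVENT carries an empty window")
    if classify(model, event.window) == "FALL":
        return Event(
            t_ms=event.t_ms,
            kind=EventKind.ALARM,
            reason=AlarmReason.FALL,
            source=event.source,
        )
    return None


def run_fall_pipeline(
    samples: Iterable[ImuSample],
    model: TrainedModel | None = None,
    config: DetectorConfig = DetectorConfig(),
    source: str = "imu",
) -> list[Event]:
    """End-to-end detection over a trace: FALL_EVENTs plus, with a model,
    the FALL alarms the classifier confirms."""
    events: list[Event] = []
    for fall_event in detect_fall_events(samples, config, source):
        events.append(fall_event)
        if model is not None:
            alarm = gateway_process(fall_event, model)
            if alarm is not None:
                events.append(alarm)
    return events
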