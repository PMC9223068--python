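"""Seeded signal generators for every detector in the package.

No public dataset exists for this sensor arrangement, so the package ships
generators that emulate the study conditions: the nine-exercise protocol
(four fall types and five activities of daily living, ADLs) for the fall
detector, the three-phase bed-exit acceleration profile for the motion
detector, in-bed rolling for its false-positive battery, and the per-posture
pressure patterns for the bed-presence classifier.

Waveform shapes (half-sine impact transients, logistic orientation
cross-fades, linear pressure cross-fades) are the simplest forms satisfying
the documented constraints — fall peaks above the 2.5 g trigger, running
peaks closer together than the 2.5 s cancellation horizon, pressure levels
matching their rule-cascade branch with margin well above the channel noise.
All generators are pure functions of (parameters, seed).

Axis convention: X up, Y to the wearer's left, Z into the body.  A lying
person therefore reads ax close to 0; rolling in bed never drives ax near
the 0.9 g standing threshold, by construction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .bed_presence import PresenceConfig, classify_pressure
from .fall_detector import DetectorConfig, FALL_ACTIVITIES, LabeledWindow, capture_window
from .sensors import ImuSample, Position, PressureSample

__all__ = [
    "SimConfig",
    "ACTIVITIES",
    "FALL_TYPES",
    "ADL_TYPES",
    "BedExitTrace",
    "gen_fall_trace",
    "gen_adl_trace",
    "gen_bed_exit",
    "gen_rolling_trace",
    "gen_pressure_sequence",
    "make_labeled_windows",
]

FALL_TYPES = ("forward", "backward", "left", "right")
ADL_TYPES = ("hit", "jump", "run_stop", "sit", "pull")
ACTIVITIES = (
    "forward_fall",
    "backward_fall",
    "left_fall",
    "right_fall",
    "hit",
    "jump",
    "run_stop",
    "sit",
    "pull",
)

#: bed geometry of the reference installation (cm): 90 x 190 mattress, edge
#: strips 20 cm from each side, middle strip at 45 cm, strip heads 57 cm from
#: the headboard.  Documentation metadata only; the rule classifier consumes
#: channel values, not geometry.
BED_GEOMETRY_CM = {"width": 90, "length": 190, "strips": (20, 45, 20), "head_offset": 57}


def _default_pressure_levels() -> dict[Position, tuple[float, float, float]]:
    return {
        Position.NO_PRESENCE: (0.0, 0.0, 0.0),
        Position.LYING_IN_MIDDLE: (300.0, 700.0, 250.0),
        Position.LYING_IN_LEFT_EDGE: (600.0, 800.0, 50.0),
        Position.LYING_IN_RIGHT_EDGE: (50.0, 800.0, 600.0),
        Position.SITTING_IN_LEFT_EDGE: (900.0, 300.0, 0.0),
        Position.SITTING_IN_RIGHT_EDGE: (0.0, 300.0, 900.0),
    }


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters; defaults encode the study conditions."""

    rate_hz: float = 50.0
    # fall transient
    fall_peak_mean_g: float = 3.2
    fall_peak_sd_g: float = 0.4
    fall_peak_min_g: float = 2.6
    pre_fall_ms: int = 1000
    impact_ms: int = 300
    quiescence_ms: int = 2600
    # running: supra-threshold steps closer together than the 1000+1500 ms
    # cancellation horizon of the trigger state machine
    adl_peak_interval_ms: int = 700
    run_peak_count: int = 8
    # channel noise
    imu_noise_sd_g: float = 0.03
    gyro_noise_sd_dps: float = 2.0
    pressure_noise_sd: float = 8.0
    # pressure patterns
    pressure_levels: dict[Position, tuple[float, float, float]] = field(
        default_factory=_default_pressure_levels
    )
    crossfade_ms: int = 400
    full_scale: float = 1023.0

    def __post_init__(self) -> None:
        if self.rate_hz < 30.0:
            raise ValueError("rate_hz must be >= 30 (movement band is 0-15 Hz)")
        if self.fall_peak_min_g <= 2.5:
            raise ValueError("fall peaks must exceed the 2.5 g trigger threshold")
        if self.quiescence_ms < 2600:
            raise ValueError("quiescence_ms must be >= 2600 (trigger needs 2500 ms + slack)")
        if self.adl_peak_interval_ms >= 2500:
            raise ValueError("running peaks must repeat within the 2500 ms cancellation horizon")
        pcfg = PresenceConfig(full_scale=self.full_scale)
        if 3 * self.pressure_noise_sd > pcfg.near_zero_eps:
            raise ValueError("pressure noise too large for the near-zero predicate margin")
        for position, levels in self.pressure_levels.items():
            got = classify_pressure(PressureSample(0, *levels), pcfg)
            if got is not position:
                raise ValueError(
                    f"pressure levels {levels} for {position.value} classify as {got.value}"
                )

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.rate_hz


def _logistic(tau: np.ndarray, center: float = 0.5, k: float = 12.0) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-k * (tau - center)))


def _to_samples(t_ms: np.ndarray, acc: np.ndarray, gyr: np.ndarray) -> list[ImuSample]:
    return [
        ImuSample(int(t), float(a[0]), float(a[1]), float(a[2]), float(g[0]), float(g[1]), float(g[2]))
        for t, a, g in zip(t_ms, acc, gyr)
    ]


def _unit(v: Sequence[float]) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


# final lying orientation, gyro axis index, and gyro sign per fall type
_FALL_GEOMETRY = {
    "forward": ((0.05, 0.0, 0.99), 1, +1.0),
    "backward": ((0.05, 0.0, -0.99), 1, -1.0),
    "left": ((0.05, 0.99, 0.0), 2, +1.0),
    "right": ((0.05, -0.99, 0.0), 2, -1.0),
}

_UPRIGHT = np.array([1.0, 0.0, 0.0])


def _grid(cfg: SimConfig, n: int, t0_ms: float = 0.0) -> np.ndarray:
    return np.round(t0_ms + np.arange(n) * cfg.dt_ms).astype(int)


def _oriented_transient(
    rng: np.random.Generator,
    cfg: SimConfig,
    d_mean: Sequence[float],
    gyro_axis: int,
    gyro_peak: float,
    peak_g: float,
    orient_jitter_sd: float = 0.08,
) -> tuple[list[ImuSample], np.ndarray]:
    """Upright segment, oriented impact transient, quiescent final orientation."""
    d = _unit(np.asarray(d_mean, float) + rng.normal(0.0, orient_jitter_sd, 3))
    n_pre = round(cfg.pre_fall_ms / cfg.dt_ms)
    n_imp = max(4, round(cfg.impact_ms / cfg.dt_ms))
    n_quiet = round(cfg.quiescence_ms / cfg.dt_ms)
    n = n_pre + n_imp + n_quiet

    acc = np.zeros((n, 3))
    gyr = np.zeros((n, 3))
    acc[:n_pre] = _UPRIGHT
    tau = (np.arange(n_imp) + 0.5) / n_imp
    w = _logistic(tau, center=0.3, k=16.0)[:, None]
    base = (1.0 - w) * _UPRIGHT + w * d
    base /= np.linalg.norm(base, axis=1, keepdims=True)
    acc[n_pre : n_pre + n_imp] = base + (peak_g - 1.0) * np.sin(np.pi * tau)[:, None] * d
    acc[n_pre + n_imp :] = d
    gyr[n_pre : n_pre + n_imp, gyro_axis] = gyro_peak * np.sin(np.pi * tau)

    acc += rng.normal(0.0, cfg.imu_noise_sd_g, acc.shape)
    gyr += rng.normal(0.0, cfg.gyro_noise_sd_dps, gyr.shape)
    # pin the impact apex so the peak magnitude is exactly peak_g
    acc[n_pre + n_imp // 2] = peak_g * d
    gyr[n_pre + n_imp // 2, :] = 0.0
    gyr[n_pre + n_imp // 2, gyro_axis] = gyro_peak
    return _to_samples(_grid(cfg, n), acc, gyr), d


def gen_fall_trace(fall_type: str, cfg: SimConfig = SimConfig(), seed=0) -> list[ImuSample]:
    """One simulated fall: upright, oriented impact above 2.5 g, then lying still.

    ``fall_type`` is one of forward/backward/left/right; the dominant lateral
    axis of the transient and the final lying orientation reflect it (left
    and right differ in the sign of the ay transient).
    """
    if fall_type not in FALL_TYPES:
        raise ValueError(f"unknown fall type {fall_type!r}, expected one of {FALL_TYPES}")
    rng = np.random.default_rng(seed)
    d_mean, axis, sign = _FALL_GEOMETRY[fall_type]
    peak = max(cfg.fall_peak_min_g, rng.normal(cfg.fall_peak_mean_g, cfg.fall_peak_sd_g))
    gyro_peak = sign * max(60.0, rng.normal(150.0, 40.0))
    samples, _ = _oriented_transient(rng, cfg, d_mean, axis, gyro_peak, peak)
    return samples


def _upright_spike_trace(
    rng: np.random.Generator,
    cfg: SimConfig,
    axis: int,
    peak_g: float,
    spike_ms: int = 200,
) -> list[ImuSample]:
    """Upright posture with one sharp supra-threshold spike along ``axis``."""
    n_pre = round(cfg.pre_fall_ms / cfg.dt_ms)
    n_spk = max(4, round(spike_ms / cfg.dt_ms))
    n_quiet = round(cfg.quiescence_ms / cfg.dt_ms)
    n = n_pre + n_spk + n_quiet
    acc = np.tile(_UPRIGHT, (n, 1))
    gyr = np.zeros((n, 3))
    tau = (np.arange(n_spk) + 0.5) / n_spk
    amp = math.sqrt(peak_g**2 - 1.0)
    acc[n_pre : n_pre + n_spk, axis] += amp * np.sin(np.pi * tau)
    acc += rng.normal(0.0, cfg.imu_noise_sd_g, acc.shape)
    gyr += rng.normal(0.0, cfg.gyro_noise_sd_dps, gyr.shape)
    apex = np.array(_UPRIGHT)
    apex[axis] += amp
    acc[n_pre + n_spk // 2] = apex  # exact peak: svm == peak_g
    return _to_samples(_grid(cfg, n), acc, gyr)


def gen_adl_trace(adl_type: str, cfg: SimConfig = SimConfig(), seed=0) -> list[ImuSample]:
    """One simulated activity of daily living.

    * ``hit`` / ``pull`` — upright with one sharp supra-threshold spike on
      the strip axis (Z for a hit on the sensor, Y for a pull);
    * ``jump`` — repeated vertical peaks kept below the 2.5 g trigger;
    * ``run_stop`` — supra-threshold footfalls every ``adl_peak_interval_ms``
      (inside the cancellation horizon) followed by an abrupt stop;
    * ``sit`` — a moderate backward transient into a reclined posture, built
      to overlap the backward-fall signature.
    """
    if adl_type not in ADL_TYPES:
        raise ValueError(f"unknown ADL type {adl_type!r}, expected one of {ADL_TYPES}")
    rng = np.random.default_rng(seed)

    if adl_type == "hit":
        peak = max(cfg.fall_peak_min_g, rng.normal(3.0, 0.3))
        return _upright_spike_trace(rng, cfg, axis=2, peak_g=peak)
    if adl_type == "pull":
        peak = max(cfg.fall_peak_min_g, rng.normal(2.9, 0.25))
        return _upright_spike_trace(rng, cfg, axis=1, peak_g=peak)

    if adl_type == "jump":
        n_pre = round(cfg.pre_fall_ms / cfg.dt_ms)
        n_bump = max(4, round(200 / cfg.dt_ms))
        n_gap = round(400 / cfg.dt_ms)
        n_post = round(1000 / cfg.dt_ms)
        n = n_pre + 3 * n_bump + 2 * n_gap + n_post
        acc = np.tile(_UPRIGHT, (n, 1))
        gyr = np.zeros((n, 3))
        tau = (np.arange(n_bump) + 0.5) / n_bump
        pos = n_pre
        for _ in range(3):
            peak = float(np.clip(rng.normal(2.1, 0.1), 1.8, 2.3))
            acc[pos : pos + n_bump, 0] += (peak - 1.0) * np.sin(np.pi * tau)
            pos += n_bump + n_gap
        acc += rng.normal(0.0, cfg.imu_noise_sd_g, acc.shape)
        gyr += rng.normal(0.0, cfg.gyro_noise_sd_dps, gyr.shape)
        return _to_samples(_grid(cfg, n), acc, gyr)

    if adl_type == "run_stop":
        n_pre = round(cfg.pre_fall_ms / cfg.dt_ms)
        n_int = round(cfg.adl_peak_interval_ms / cfg.dt_ms)
        n_bump = max(4, round(160 / cfg.dt_ms))
        n_quiet = round(cfg.quiescence_ms / cfg.dt_ms)
        n = n_pre + cfg.run_peak_count * n_int + n_quiet
        acc = np.tile(_UPRIGHT, (n, 1))
        gyr = np.zeros((n, 3))
        tau = (np.arange(n_bump) + 0.5) / n_bump
        apices = []
        for k in range(cfg.run_peak_count):
            peak = max(cfg.fall_peak_min_g, rng.normal(2.9, 0.2))
            pos = n_pre + k * n_int
            acc[pos : pos + n_bump, 0] += (peak - 1.0) * np.sin(np.pi * tau)
            apices.append((pos + n_bump // 2, peak))
        acc += rng.normal(0.0, cfg.imu_noise_sd_g, acc.shape)
        gyr += rng.normal(0.0, cfg.gyro_noise_sd_dps, gyr.shape)
        for idx, peak in apices:
            acc[idx] = (peak, 0.0, 0.0)
        return _to_samples(_grid(cfg, n), acc, gyr)

    # sit: moderate transient, reclined end orientation, backward rotation —
    # deliberately adjacent to the backward-fall signature
    peak = max(cfg.fall_peak_min_g, rng.normal(2.8, 0.15))
    gyro_peak = -max(40.0, rng.normal(110.0, 30.0))
    samples, _ = _oriented_transient(rng, cfg, (0.22, 0.0, -0.95), 1, gyro_peak, peak)
    return samples


@dataclass(frozen=True)
class BedExitTrace:
    """Synchronized IMU + pressure streams for one bed exit, with truth."""

    side: str
    imu: tuple[ImuSample, ...]
    pressure: tuple[PressureSample, ...]
    #: phase name -> (start_ms, end_ms) of the IMU profile
    phases: dict[str, tuple[int, int]]
    #: ground-truth (start_ms, Position) of the pressure pattern
    positions: tuple[tuple[int, Position], ...]


def gen_bed_exit(side: str, cfg: SimConfig = SimConfig(), seed=0) -> BedExitTrace:
    """A full bed exit: lying -> sitting on the chosen edge -> standing -> walking.

    The acceleration profile follows the observed trajectory (ax near 0 and
    az near 1 while lying, reversing as the person gets up until ax
    oscillates around 0.9-1 with az within +/-0.4); the pressure stream walks
    LYING_IN_MIDDLE -> LYING on the exit side -> SITTING on that side ->
    NO_PRESENCE, each posture held well beyond the one-second debounce.
    """
    if side not in ("left", "right"):
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    imu_ss, pressure_ss = ss.spawn(2)
    rng = np.random.default_rng(imu_ss)

    phases = {
        "lying": (0, 4600),
        "lying_sitting": (4600, 5400),
        "sitting": (5400, 6600),
        "sitting_standing": (6600, 7400),
        "standing": (7400, 8400),
        "standing_walking": (8400, 10000),
    }
    lying = np.array([0.05, 0.0, 0.98])
    sitting = np.array([0.75, 0.0, 0.50])
    standing = np.array([0.97, 0.0, 0.05])

    n = round(phases["standing_walking"][1] / cfg.dt_ms)
    t = _grid(cfg, n)
    acc = np.zeros((n, 3))
    gyr = np.zeros((n, 3))

    def fill_const(span: tuple[int, int], vec: np.ndarray) -> None:
        m = (t >= span[0]) & (t < span[1])
        acc[m] = vec

    def fill_transition(span: tuple[int, int], a: np.ndarray, b: np.ndarray) -> None:
        m = (t >= span[0]) & (t < span[1])
        tau = (t[m] - span[0]) / (span[1] - span[0])
        w = _logistic(tau, center=0.5, k=10.0)[:, None]
        acc[m] = (1.0 - w) * a + w * b
        gyr[m, 1] = rng.normal(55.0, 10.0) * np.sin(np.pi * tau)

    fill_const(phases["lying"], lying)
    fill_transition(phases["lying_sitting"], lying, sitting)
    fill_const(phases["sitting"], sitting)
    fill_transition(phases["sitting_standing"], sitting, standing)
    fill_const(phases["standing"], standing)
    walk = (t >= phases["standing_walking"][0]) & (t < phases["standing_walking"][1])
    stride = 2.0 * np.pi * 1.8 * (t[walk] - phases["standing_walking"][0]) / 1000.0
    acc[walk, 0] = standing[0] + 0.06 * np.sin(stride)
    acc[walk, 2] = standing[2] + 0.12 * np.sin(stride + 1.0)
    gyr[walk, 1] = 25.0 * np.sin(stride)

    acc += rng.normal(0.0, cfg.imu_noise_sd_g, acc.shape)
    gyr += rng.normal(0.0, cfg.gyro_noise_sd_dps, gyr.shape)
    imu = _to_samples(t, acc, gyr)

    lying_edge = Position.LYING_IN_LEFT_EDGE if side == "left" else Position.LYING_IN_RIGHT_EDGE
    sitting_edge = (
        Position.SITTING_IN_LEFT_EDGE if side == "left" else Position.SITTING_IN_RIGHT_EDGE
    )
    sequence = [Position.LYING_IN_MIDDLE, lying_edge, sitting_edge, Position.NO_PRESENCE]
    holds = [3000, 2000, 2000, 2000]
    pressure = gen_pressure_sequence(sequence, holds, cfg, pressure_ss)
    starts = np.concatenate(([0], np.cumsum(holds)[:-1])).astype(int)
    return BedExitTrace(
        side=side,
        imu=tuple(imu),
        pressure=tuple(pressure),
        phases=phases,
        positions=tuple((int(s), p) for s, p in zip(starts, sequence)),
    )


def gen_rolling_trace(cfg: SimConfig = SimConfig(), seed=0, cycles: int = 4) -> list[ImuSample]:
    """In-bed rolling: right side -> supine -> left side, repeated.

    ax stays near 0 throughout (bounded far below the 0.9 g standing
    threshold), so the motion detector must stay silent on this trace.
    """
    rng = np.random.default_rng(seed)
    orientations = [
        np.array([0.05, -0.85, 0.50]),
        np.array([0.05, 0.0, 0.98]),
        np.array([0.05, 0.85, 0.50]),
        np.array([0.05, 0.0, 0.98]),
    ]
    hold_n = round(1000 / cfg.dt_ms)
    fade_n = round(600 / cfg.dt_ms)
    segs: list[np.ndarray] = []
    gyrs: list[np.ndarray] = []
    prev = orientations[-1]
    for _ in range(cycles):
        for target in orientations:
            tau = (np.arange(fade_n) + 0.5) / fade_n
            w = _logistic(tau, center=0.5, k=10.0)[:, None]
            fade = (1.0 - w) * prev + w * target
            g = np.zeros((fade_n + hold_n, 3))
            g[:fade_n, 2] = rng.normal(50.0, 10.0) * np.sin(np.pi * tau)
            segs.append(np.vstack([fade, np.tile(target, (hold_n, 1))]))
            gyrs.append(g)
            prev = target
    acc = np.vstack(segs)
    gyr = np.vstack(gyrs)
    acc += rng.normal(0.0, cfg.imu_noise_sd_g, acc.shape)
    gyr += rng.normal(0.0, cfg.gyro_noise_sd_dps, gyr.shape)
    return _to_samples(_grid(cfg, len(acc)), acc, gyr)


def gen_pressure_sequence(
    positions: Sequence[Position],
    hold_ms: Sequence[int],
    cfg: SimConfig = SimConfig(),
    seed=0,
    min_hold_ms: int = 1000,
) -> list[PressureSample]:
    """Pressure stream walking through ``positions`` with the given holds.

    Channel levels per posture come from ``cfg.pressure_levels``; consecutive
    holds are joined by a linear cross-fade of ``cfg.crossfade_ms`` and all
    channels carry Gaussian noise clipped to [0, full_scale].
    """
    if len(positions) != len(hold_ms):
        raise ValueError("positions and hold_ms must have equal length")
    for p in positions:
        if p is Position.NOT_RECOGNIZED:
            raise ValueError("NOT_RECOGNIZED has no generated pattern")
        if p not in cfg.pressure_levels:
            raise ValueError(f"no configured pressure levels for {p.value}")
    for p, h in zip(positions, hold_ms):
        if h <= min_hold_ms:
            warnings.warn(
                f"hold of {h} ms for {p.value} does not exceed the {min_hold_ms} ms "
                "debounce and may be unrecoverable",
                stacklevel=2,
            )

    rng = np.random.default_rng(seed)
    starts = np.concatenate(([0], np.cumsum(hold_ms))).astype(float)
    n = round(starts[-1] / cfg.dt_ms)
    t = _grid(cfg, n)
    levels = np.array([cfg.pressure_levels[p] for p in positions], dtype=float)
    values = np.empty((n, 3))
    seg = np.clip(np.searchsorted(starts, t, side="right") - 1, 0, len(positions) - 1)
    for i in range(len(positions)):
        m = seg == i
        values[m] = levels[i]
        if i > 0 and cfg.crossfade_ms > 0:
            fade = m & (t < starts[i] + cfg.crossfade_ms)
            tau = ((t[fade] - starts[i]) / cfg.crossfade_ms)[:, None]
            values[fade] = (1.0 - tau) * levels[i - 1] + tau * levels[i]
    values += rng.normal(0.0, cfg.pressure_noise_sd, values.shape)
    values = np.clip(values, 0.0, cfg.full_scale)
    return [PressureSample(int(tt), float(v[0]), float(v[1]), float(v[2])) for tt, v in zip(t, values)]


def make_labeled_windows(
    reps: int = 10,
    cfg: SimConfig = SimConfig(),
    seed=0,
    detector: DetectorConfig = DetectorConfig(),
) -> list[LabeledWindow]:
    """Simulated training/testing corpus: ``reps`` traces per activity.

    Each trace is reduced to its captured window: the trigger state machine's
    log when the trace fires it, otherwise the one-second stretch starting at
    the magnitude peak (jumps never fire the trigger).
    """
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    children = iter(ss.spawn(len(ACTIVITIES) * reps))
    windows: list[LabeledWindow] = []
    for activity in ACTIVITIES:
        for _ in range(reps):
            child = next(children)
            if activity in FALL_ACTIVITIES:
                trace = gen_fall_trace(activity.removesuffix("_fall"), cfg, child)
                label = "FALL"
            else:
                trace = gen_adl_trace(activity, cfg, child)
                label = "ADL"
            window = capture_window(trace, detector)
            windows.append(LabeledWindow(window=tuple(window), label=label, activity=activity))
    return windows
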