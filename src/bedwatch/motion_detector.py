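"""Threshold detection of the stand-up/walk posture from the waist IMU.

With the X axis pointing up and Z into the body, lying in bed reads ax close
to 0 and az close to 1, while standing reverses them: ax oscillates around
0.9-1.0 and az stays within +/-0.4.  A sample whose ax exceeds ``x_min`` with
az strictly inside (-z_abs_max, z_abs_max) therefore indicates that the
wearer has stood up or is walking.  The Y component is ignored: it would only
discriminate the exit side, which is irrelevant for alerting.

The raw predicate would hold on every sample while the wearer stands, so
event emission is rate-limited: a MOVEMENT_EVENT is emitted when the
predicate holds and no event was emitted within the previous ``rearm_ms``.
A sustained stand keeps refreshing the movement evidence once per rearm
period, which is what the fusion stage's recency window consumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .sensors import Event, EventKind, ImuSample

__all__ = ["MotionConfig", "is_moving", "motion_events"]


@dataclass(frozen=True)
class MotionConfig:
    x_min: float = 0.9
    z_abs_max: float = 0.4
    rearm_ms: int = 2000

    def __post_init__(self) -> None:
        if self.x_min <= 0 or self.z_abs_max <= 0:
            raise ValueError("x_min and z_abs_max must be > 0")
        if self.rearm_ms <= 0:
            raise ValueError("rearm_ms must be > 0")


def is_moving(sample: ImuSample, cfg: MotionConfig = MotionConfig()) -> bool:
    """True iff ax > x_min and -z_abs_max < az < z_abs_max (strict)."""
    return sample.ax > cfg.x_min and -cfg.z_abs_max < sample.az < cfg.z_abs_max


def motion_events(
    stream: Iterable[ImuSample],
    cfg: MotionConfig = MotionConfig(),
    source: str = "imu",
) -> list[Event]:
    """Emit rate-limited MOVEMENT_EVENTs over a time-ordered trace."""
    events: list[Event] = []
    last_emit: int | None = None
    prev_t: int | None = None
    for sample in stream:
        if prev_t is not None and sample.t_ms <= prev_t:
            raise ValueError(f"out-of-order sample at t_ms={sample.t_ms}")
        prev_t = sample.t_ms
        if is_moving(sample, cfg) and (last_emit is None or sample.t_ms - last_emit > cfg.rearm_ms):
            events.append(Event(t_ms=sample.t_ms, kind=EventKind.MOVEMENT_EVENT, source=source))
            last_emit = sample.t_ms
    return events
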