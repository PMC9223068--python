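"""Fusion of bed-presence and movement streams into risk alarms.

Two situations are reported to the caregiver:

* BED_EXIT — the stable bed position became NO_PRESENCE (the person left the
  bed), regardless of movement evidence;
* EXIT_INTENT — the person is sitting on a bed edge *and* there is concurrent
  movement evidence from the wearable.  Requiring both sources cuts false
  positives.

"Concurrent" uses a sliding recency window: movement is active at time t iff
a MOVEMENT_EVENT occurred in (t - movement_window_ms, t].  The fused rule is
re-evaluated at every stable position change and at every movement event, and
at most one alarm is raised per presence episode (re-armed when the position
changes).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .sensors import AlarmReason, Event, EventKind, Position

__all__ = ["FusionConfig", "fuse", "monitor"]

_SITTING = (Position.SITTING_IN_LEFT_EDGE, Position.SITTING_IN_RIGHT_EDGE)


@dataclass(frozen=True)
class FusionConfig:
    movement_window_ms: int = 2000

    def __post_init__(self) -> None:
        if self.movement_window_ms <= 0:
            raise ValueError("movement_window_ms must be > 0")


def fuse(presence: Position, movement_active: bool) -> AlarmReason | None:
    """Alarm decision for one (stable position, movement evidence) pair."""
    if presence is Position.NOT_RECOGNIZED:
        raise ValueError("NOT_RECOGNIZED is not a stable position")
    if presence is Position.NO_PRESENCE:
        return AlarmReason.BED_EXIT
    if presence in _SITTING and movement_active:
        return AlarmReason.EXIT_INTENT
    return None


def monitor(
    presence_events: Sequence[Event],
    movement_events: Sequence[Event],
    cfg: FusionConfig = FusionConfig(),
    source: str = "fusion",
) -> list[Event]:
    """Merge the two event streams by timestamp and raise alarms.

    At equal timestamps the movement event is processed first, so movement
    arriving at the same instant as a position change counts as concurrent.
    """
    for ev in presence_events:
        if ev.kind is not EventKind.PRESENCE:
            raise ValueError(f"presence stream contains a {ev.kind.value}")
    for ev in movement_events:
        if ev.kind is not EventKind.MOVEMENT_EVENT:
            raise ValueError(f"movement stream contains a {ev.kind.value}")

    merged = sorted(
        list(presence_events) + list(movement_events),
        key=lambda e: (e.t_ms, 0 if e.kind is EventKind.MOVEMENT_EVENT else 1),
    )

    alarms: list[Event] = []
    position: Position | None = None
    last_movement: int | None = None
    episode_alarmed = False

    def movement_active_at(t: int) -> bool:
        return last_movement is not None and t - cfg.movement_window_ms < last_movement <= t

    for ev in merged:
        if ev.kind is EventKind.MOVEMENT_EVENT:
            last_movement = ev.t_ms
            if position is None or episode_alarmed:
                continue
            reason = fuse(position, True)
        else:
            position = ev.position
            episode_alarmed = False
            reason = fuse(position, movement_active_at(ev.t_ms))
        if reason is not None:
            alarms.append(Event(t_ms=ev.t_ms, kind=EventKind.ALARM, reason=reason, source=source))
            episode_alarmed = True
    return alarms
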