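"""Bed-position classification from the three pressure strips.

Each raw sample is mapped to a posture by a fixed rule cascade evaluated in
order, first match wins:

1. all three strips near zero               -> NO_PRESENCE
2. middle strictly greatest and both edge-to-middle separations exceed the
   edge-to-edge separation                  -> LYING_IN_MIDDLE
3. one edge dominant, the opposite edge near zero, and the dominant edge far
   above the middle                         -> SITTING on that edge
4. middle above the dominant edge and the edge-to-middle separation smaller
   than the edge-to-edge separation         -> LYING on that edge
5. otherwise                                -> NOT_RECOGNIZED

"near zero" means <= near_zero_eps, "far above" means an absolute difference
>= large_diff_delta, and all other comparisons are strict, so exact ties fall
through to NOT_RECOGNIZED.  A raw label only becomes a stable posture after
persisting for longer than min_hold_ms (debouncing), which suppresses the
patternless readings produced while the person changes position.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .sensors import Event, EventKind, Position, PressureSample

__all__ = ["PresenceConfig", "classify_pressure", "debounce", "presence_pipeline"]


@dataclass(frozen=True)
class PresenceConfig:
    """Thresholds of the rule cascade and the debouncing hold time.

    ``near_zero_eps`` and ``large_diff_delta`` default to 5% and 40% of the
    ADC full scale; both are in raw counts.
    """

    full_scale: float = 1023.0
    near_zero_eps: float | None = None
    large_diff_delta: float | None = None
    min_hold_ms: int = 1000

    def __post_init__(self) -> None:
        if self.near_zero_eps is None:
            object.__setattr__(self, "near_zero_eps", 0.05 * self.full_scale)
        if self.large_diff_delta is None:
            object.__setattr__(self, "large_diff_delta", 0.40 * self.full_scale)
        if not (0 <= self.near_zero_eps < self.large_diff_delta <= self.full_scale):
            raise ValueError(
                "require 0 <= near_zero_eps < large_diff_delta <= full_scale, got "
                f"eps={self.near_zero_eps}, delta={self.large_diff_delta}, "
                f"full_scale={self.full_scale}"
            )
        if self.min_hold_ms <= 0:
            raise ValueError("min_hold_ms must be > 0")


def classify_pressure(sample: PressureSample, cfg: PresenceConfig = PresenceConfig()) -> Position:
    """Map one raw (left, middle, right) reading to a posture label."""
    left, middle, right = sample.left, sample.middle, sample.right
    for name, v in (("left", left), ("middle", middle), ("right", right)):
        if v < 0:
            raise ValueError(f"negative pressure count {name}={v}")

    eps = cfg.near_zero_eps
    delta = cfg.large_diff_delta

    def near0(v: float) -> bool:
        return v <= eps

    def diff(a: float, b: float) -> float:
        return abs(a - b)

    if near0(middle) and near0(left) and near0(right):
        return Position.NO_PRESENCE
    if (
        middle > right
        and middle > left
        and diff(right, middle) > diff(left, right)
        and diff(left, middle) > diff(left, right)
    ):
        return Position.LYING_IN_MIDDLE
    if left > right and left > middle and near0(right) and diff(left, middle) >= delta:
        return Position.SITTING_IN_LEFT_EDGE
    if left > right and middle > left and diff(left, middle) < diff(right, left):
        return Position.LYING_IN_LEFT_EDGE
    if right > left and right > middle and near0(left) and diff(right, middle) >= delta:
        return Position.SITTING_IN_RIGHT_EDGE
    if right > left and middle > right and diff(right, middle) < diff(right, left):
        return Position.LYING_IN_RIGHT_EDGE
    return Position.NOT_RECOGNIZED


def debounce(
    labels: Iterable[tuple[int, Position]],
    cfg: PresenceConfig = PresenceConfig(),
    source: str = "bed",
) -> list[Event]:
    """Turn the raw label stream into stable PRESENCE events.

    NOT_RECOGNIZED labels are dropped without resetting the hold timer (a
    patternless transition reading implies no change of position).  A new
    posture is emitted once the same raw label has persisted for strictly
    longer than ``min_hold_ms``, measured from the first sample of the run.
    """
    events: list[Event] = []
    stable: Position | None = None
    run_label: Position | None = None
    run_start: int | None = None
    for t, label in labels:
        if label is Position.NOT_RECOGNIZED:
            continue
        if label is not run_label:
            run_label = label
            run_start = t
        if label is not stable and t - run_start > cfg.min_hold_ms:
            stable = label
            events.append(Event(t_ms=t, kind=EventKind.PRESENCE, position=label, source=source))
    return events


def presence_pipeline(
    stream: Sequence[PressureSample],
    cfg: PresenceConfig = PresenceConfig(),
    source: str = "bed",
    bus=None,
    topic: str = "bed-presence",
) -> list[Event]:
    """Classify every sample, debounce, and optionally publish the events."""
    raw = ((s.t_ms, classify_pressure(s, cfg)) for s in stream)
    events = debounce(raw, cfg, source)
    if bus is not None:
        for ev in events:
            bus.publish(topic, ev)
    return events
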