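"""Domain types, stream I/O, and the in-process event bus.

The monitored person wears an inertial measurement unit (IMU) at the waist,
oriented so that the X axis points up (perpendicular to the ground), Y points
to the wearer's left, and Z is parallel to the ground pointing into the body.
Acceleration is expressed in g, angular velocity in deg/s.  Three pressure
strips run across the bed width under the mattress; each reports a raw,
dimensionless ADC count that grows with the applied force.

Streams are exchanged as plain CSV files and detector output as JSON-lines
event logs.  Distribution concerns (BLE announcements, multicast groups) are
replaced by an in-process publish/subscribe bus with ordered, lossless
delivery.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Sequence

__all__ = [
    "Position",
    "EventKind",
    "AlarmReason",
    "ImuSample",
    "PressureSample",
    "Event",
    "StreamFormatError",
    "TopicError",
    "svm",
    "read_imu_stream",
    "write_imu_stream",
    "read_pressure_stream",
    "write_pressure_stream",
    "read_events",
    "write_events",
    "EventBus",
]

IMU_HEADER = ["t_ms", "ax_g", "ay_g", "az_g", "gx_dps", "gy_dps", "gz_dps"]
PRESSURE_HEADER = ["t_ms", "left", "middle", "right"]

#: floats are written with 6 significant digits, beyond sensor resolution
FLOAT_FMT = "%.6g"


class StreamFormatError(ValueError):
    """A stream file violates the CSV dialect or its ordering invariants."""


class TopicError(KeyError):
    """An event was published to (or requested from) an unregistered topic."""


class Position(str, Enum):
    """Stable postures the bed-presence classifier can report.

    NOT_RECOGNIZED marks a raw reading that matches no known pattern; it is
    never emitted as a debounced (stable) position.
    """

    NO_PRESENCE = "NO_PRESENCE"
    SITTING_IN_LEFT_EDGE = "SITTING_IN_LEFT_EDGE"
    SITTING_IN_RIGHT_EDGE = "SITTING_IN_RIGHT_EDGE"
    LYING_IN_LEFT_EDGE = "LYING_IN_LEFT_EDGE"
    LYING_IN_RIGHT_EDGE = "LYING_IN_RIGHT_EDGE"
    LYING_IN_MIDDLE = "LYING_IN_MIDDLE"
    NOT_RECOGNIZED = "NOT_RECOGNIZED"


class EventKind(str, Enum):
    FALL_EVENT = "FALL_EVENT"
    MOVEMENT_EVENT = "MOVEMENT_EVENT"
    PRESENCE = "PRESENCE"
    ALARM = "ALARM"


class AlarmReason(str, Enum):
    BED_EXIT = "BED_EXIT"
    EXIT_INTENT = "EXIT_INTENT"
    FALL = "FALL"


def _require_finite(name: str, value: float) -> None:
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")


@dataclass(frozen=True)
class ImuSample:
    """One timestamped accelerometer + gyroscope reading."""

    t_ms: int
    ax: float
    ay: float
    az: float
    gx: float
    gy: float
    gz: float

    def __post_init__(self) -> None:
        for name in ("ax", "ay", "az", "gx", "gy", "gz"):
            _require_finite(name, getattr(self, name))


@dataclass(frozen=True)
class PressureSample:
    """One timestamped (left, middle, right) pressure-strip reading."""

    t_ms: int
    left: float
    middle: float
    right: float

    def __post_init__(self) -> None:
        for name in ("left", "middle", "right"):
            value = getattr(self, name)
            _require_finite(name, value)
            if value < 0:
                raise ValueError(f"pressure count {name} must be >= 0, got {value}")


@dataclass(frozen=True)
class Event:
    """A typed system event.

    ``position`` is set for PRESENCE events, ``reason`` for ALARM events.
    FALL_EVENTs additionally carry the captured sample window in ``window``;
    the window never appears in the serialized JSON form.
    """

    t_ms: int
    kind: EventKind
    position: Position | None = None
    reason: AlarmReason | None = None
    source: str = ""
    window: tuple[ImuSample, ...] | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.kind is EventKind.PRESENCE and self.position is None:
            raise ValueError("PRESENCE events require a position")
        if self.kind is EventKind.ALARM and self.reason is None:
            raise ValueError("ALARM events require a reason")
        if self.kind is not EventKind.PRESENCE and self.position is not None:
            raise ValueError(f"{self.kind.value} events must not carry a position")
        if self.kind is not EventKind.ALARM and self.reason is not None:
            raise ValueError(f"{self.kind.value} events must not carry a reason")

    def to_dict(self) -> dict:
        out: dict = {"t_ms": self.t_ms, "kind": self.kind.value}
        if self.position is not None:
            out["position"] = self.position.value
        if self.reason is not None:
            out["reason"] = self.reason.value
        if self.source:
            out["source"] = self.source
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "Event":
        return cls(
            t_ms=int(d["t_ms"]),
            kind=EventKind(d["kind"]),
            position=Position(d["position"]) if "position" in d else None,
            reason=AlarmReason(d["reason"]) if "reason" in d else None,
            source=d.get("source", ""),
        )


def svm(ax: float, ay: float, az: float) -> float:
    """Signal vector magnitude sqrt(ax^2 + ay^2 + az^2) of a tri-axial reading.

    The fall trigger compares this magnitude against a 2.5 g threshold.
    """
    for name, v in (("ax", ax), ("ay", ay), ("az", az)):
        _require_finite(name, v)
    return math.sqrt(ax * ax + ay * ay + az * az)


def _read_rows(path: str | Path, header: Sequence[str]):
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            got = next(reader)
        except StopIteration:
            raise StreamFormatError(f"{path}: empty file, expected header {','.join(header)}")
        if got != list(header):
            raise StreamFormatError(
                f"{path}: bad header {','.join(got)!r}, expected {','.join(header)!r}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise StreamFormatError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(row)}"
                )
            yield lineno, row


def _check_monotonic(path, lineno: int, t: int, prev_t: int | None) -> None:
    if prev_t is not None and t <= prev_t:
        raise StreamFormatError(
            f"{path}:{lineno}: t_ms {t} not strictly increasing (previous {prev_t})"
        )


def read_imu_stream(path: str | Path) -> list[ImuSample]:
    """Read an IMU CSV, validating field count and strict time ordering."""
    samples: list[ImuSample] = []
    prev_t: int | None = None
    for lineno, row in _read_rows(path, IMU_HEADER):
        try:
            t = int(row[0])
            values = [float(x) for x in row[1:]]
        except ValueError as exc:
            raise StreamFormatError(f"{path}:{lineno}: malformed row: {exc}") from exc
        _check_monotonic(path, lineno, t, prev_t)
        prev_t = t
        samples.append(ImuSample(t, *values))
    return samples


def write_imu_stream(samples: Iterable[ImuSample], path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(IMU_HEADER)
        for s in samples:
            writer.writerow(
                [s.t_ms] + [FLOAT_FMT % v for v in (s.ax, s.ay, s.az, s.gx, s.gy, s.gz)]
            )


def read_pressure_stream(path: str | Path) -> list[PressureSample]:
    samples: list[PressureSample] = []
    prev_t: int | None = None
    for lineno, row in _read_rows(path, PRESSURE_HEADER):
        try:
            t = int(row[0])
            values = [float(x) for x in row[1:]]
        except ValueError as exc:
            raise StreamFormatError(f"{path}:{lineno}: malformed row: {exc}") from exc
        _check_monotonic(path, lineno, t, prev_t)
        prev_t = t
        samples.append(PressureSample(t, *values))
    return samples


def write_pressure_stream(samples: Iterable[PressureSample], path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(PRESSURE_HEADER)
        for s in samples:
            writer.writerow([s.t_ms] + [FLOAT_FMT % v for v in (s.left, s.middle, s.right)])


def read_events(path: str | Path) -> list[Event]:
    events = []
    with Path(path).open(encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                events.append(Event.from_dict(json.loads(line)))
    return events


def write_events(events: Iterable[Event], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for ev in events:
            fh.write(json.dumps(ev.to_dict()) + "\n")


class EventBus:
    """Minimal in-process publish/subscribe bus.

    Delivery is lossless and preserves per-topic publication order.  Topics
    must be registered before use; publishing to an unknown topic is a
    configuration error.
    """

    def __init__(self, topics: Iterable[str] = ()) -> None:
        self._subscribers: dict[str, list[list[Event]]] = {}
        for t in topics:
            self.register(t)

    def register(self, topic: str) -> None:
        self._subscribers.setdefault(topic, [])

    @property
    def topics(self) -> tuple[str, ...]:
        return tuple(self._subscribers)

    def publish(self, topic: str, event: Event) -> None:
        if topic not in self._subscribers:
            raise TopicError(f"unregistered topic {topic!r}")
        for queue in self._subscribers[topic]:
            queue.append(event)

    def subscribe(self, topic: str) -> "Subscription":
        if topic not in self._subscribers:
            raise TopicError(f"unregistered topic {topic!r}")
        queue: list[Event] = []
        self._subscribers[topic].append(queue)
        return Subscription(queue)


class Subscription:
    """Iterator over events delivered to one subscriber, in order."""

    def __init__(self, queue: list[Event]) -> None:
        self._queue = queue

    def __iter__(self) -> Iterator[Event]:
        while self._queue:
            yield self._queue.pop(0)

    def __len__(self) -> int:
        return len(self._queue)
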