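"""Reading, writing and segmenting CASAS-dialect smart-home event logs.

A CASAS annotated event log is line-oriented text.  Each non-blank line is a
whitespace-delimited record::

    2012-07-18 13:47:05.000054 M012 ON
    2012-07-18 13:47:42.123    D002 OPEN Bathe begin
    2012-07-18 13:48:01.5      T101 21.5

i.e. date, time, sensor id, sensor message, and optionally an activity label
(possibly multi-word) followed by a ``begin``/``end`` marker.  Motion (M*) and
door (D*) sensors emit the categorical states ON/OFF/OPEN/CLOSE; environmental
sensors (temperature, light, ...) emit decimal numerals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from datetime import datetime
from typing import Iterable, Iterator, TextIO

__all__ = [
    "CATEGORICAL_STATES",
    "ACTIVATION_STATES",
    "CasasParseError",
    "SensorEvent",
    "ActivityInstance",
    "parse_events",
    "write_events",
    "segment_instances",
]

#: the four categorical sensor states (case-insensitive on input)
CATEGORICAL_STATES = frozenset({"ON", "OFF", "OPEN", "CLOSE"})
#: the states counted as activations by the featurizer
ACTIVATION_STATES = frozenset({"ON", "OPEN"})

_MARKERS = frozenset({"begin", "end"})

_TIME_FORMATS = ("%Y-%m-%d %H:%M:%S.%f", "%Y-%m-%d %H:%M:%S")


class CasasParseError(ValueError):
    """A malformed line in a CASAS event log; carries the 1-based line number."""

    def __init__(self, line_number: int, message: str):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


@dataclass(frozen=True)
class SensorEvent:
    """One sensor reading: a state change or numeric sample, optionally annotated."""

    timestamp: datetime
    sensor_id: str
    message: str
    annotation: tuple[str, str] | None = None  # (activity label, "begin"|"end")
    line_number: int | None = field(default=None, compare=False)

    @property
    def is_categorical(self) -> bool:
        """True when the message is one of ON/OFF/OPEN/CLOSE."""
        return self.message.upper() in CATEGORICAL_STATES

    @property
    def is_activation(self) -> bool:
        """True for ON/OPEN — the transitions the count featurizer tallies."""
        return self.message.upper() in ACTIVATION_STATES

    @property
    def numeric_value(self) -> float:
        if self.is_categorical:
            raise ValueError(f"event message {self.message!r} is categorical")
        return float(self.message)


@dataclass(frozen=True)
class ActivityInstance:
    """A labeled contiguous slice of events between begin/end annotations."""

    label: str
    events: tuple[SensorEvent, ...]
    start: datetime
    end: datetime

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError("activity label must be non-empty")
        if self.start > self.end:
            raise ValueError(f"instance {self.label!r}: start after end")


def _parse_timestamp(date_s: str, time_s: str, line_number: int) -> datetime:
    text = f"{date_s} {time_s}"
    for fmt in _TIME_FORMATS:
        try:
            return datetime.strptime(text, fmt)
        except ValueError:
            continue
    raise CasasParseError(line_number, f"unparseable timestamp {text!r}")


def _validate_message(message: str, line_number: int) -> None:
    if message.upper() in CATEGORICAL_STATES:
        return
    try:
        float(message)
    except ValueError:
        raise CasasParseError(
            line_number,
            f"message {message!r} is neither a categorical state "
            f"({'/'.join(sorted(CATEGORICAL_STATES))}) nor numeric",
        ) from None


def parse_events(
    source: Iterable[str] | TextIO,
    *,
    strict_order: bool = False,
) -> list[SensorEvent]:
    """Parse a CASAS event log into :class:`SensorEvent` records.

    Fields are split on runs of whitespace: date, time, sensor id, message,
    then optionally an activity label (everything up to the marker, so
    multi-word labels survive) and a ``begin``/``end`` marker.  Out-of-order
    timestamps are reported with a warning (or an error when
    ``strict_order``), never silently reordered.
    """
    events: list[SensorEvent] = []
    previous: datetime | None = None
    for line_number, raw in enumerate(source, start=1):
        line = raw.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) < 4:
            raise CasasParseError(
                line_number, f"expected >=4 whitespace-delimited fields, got {len(parts)}"
            )
        timestamp = _parse_timestamp(parts[0], parts[1], line_number)
        sensor_id, message = parts[2], parts[3]
        _validate_message(message, line_number)
        annotation: tuple[str, str] | None = None
        if len(parts) > 4:
            marker = parts[-1].lower()
            if marker not in _MARKERS:
                raise CasasParseError(
                    line_number, f"unknown begin/end marker {parts[-1]!r}"
                )
            label = " ".join(parts[4:-1])
            if not label:
                raise CasasParseError(line_number, "marker present but label missing")
            annotation = (label, marker)
        if previous is not None and timestamp < previous:
            msg = f"line {line_number}: timestamp {timestamp} precedes previous event"
            if strict_order:
                raise CasasParseError(line_number, "out-of-order timestamp")
            warnings.warn(msg, stacklevel=2)
        previous = timestamp
        events.append(
            SensorEvent(timestamp, sensor_id, message, annotation, line_number)
        )
    return events


def format_event(event: SensorEvent) -> str:
    """Render one event back into the CASAS text dialect."""
    ts = event.timestamp
    stamp = ts.strftime("%Y-%m-%d %H:%M:%S.%f")
    parts = [stamp, event.sensor_id, event.message]
    if event.annotation is not None:
        label, marker = event.annotation
        parts.append(f"{label} {marker}")
    return " ".join(parts)


def write_events(events: Iterable[SensorEvent], sink: TextIO) -> None:
    """Write events in the same dialect :func:`parse_events` reads."""
    for event in events:
        sink.write(format_event(event) + "\n")


def _iter_spans(
    events: list[SensorEvent],
) -> Iterator[tuple[str, int, int]]:
    """Yield (label, begin index, end index) for each matched begin/end pair."""
    open_spans: dict[str, int] = {}
    for i, event in enumerate(events):
        if event.annotation is None:
            continue
        label, marker = event.annotation
        if marker == "begin":
            if label in open_spans:
                warnings.warn(
                    f"{label!r}: second 'begin' before 'end' "
                    f"(line {event.line_number}); earlier span dropped",
                    stacklevel=3,
                )
            open_spans[label] = i
        else:  # end
            if label not in open_spans:
                warnings.warn(
                    f"{label!r}: 'end' without matching 'begin' "
                    f"(line {event.line_number}); skipped",
                    stacklevel=3,
                )
                continue
            yield label, open_spans.pop(label), i
    for label, i in open_spans.items():
        warnings.warn(
            f"{label!r}: 'begin' without matching 'end' "
            f"(line {events[i].line_number}); skipped",
            stacklevel=3,
        )


def segment_instances(events: list[SensorEvent]) -> list[ActivityInstance]:
    """Cut a time-ordered event list into labeled activity instances.

    One instance per matched ``label begin ... label end`` pair.  An instance
    contains exactly the events whose timestamps lie in the closed interval
    between its begin and end annotations, so the annotated events themselves
    belong to the activity.  Interleaved instances of different labels each
    receive the events in their own span (events in the overlap appear in
    both).  Unmatched annotations are reported with a warning and skipped.
    """
    instances = []
    for label, begin_idx, end_idx in _iter_spans(events):
        start = events[begin_idx].timestamp
        end = events[end_idx].timestamp
        span = tuple(e for e in events if start <= e.timestamp <= end)
        instances.append(ActivityInstance(label, span, start, end))
    instances.sort(key=lambda inst: inst.start)
    return instances


def strip_annotations(events: Iterable[SensorEvent]) -> list[SensorEvent]:
    """Copy of the event list with all begin/end annotations removed."""
    return [replace(e, annotation=None) for e in events]
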