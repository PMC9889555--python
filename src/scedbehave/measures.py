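"""Composable data-collection measures and direct-observation recording.

A :class:`Measure` is an ordered list of items of six kinds: direct
observation, choice, number, range, four-quadrant and free text.  Direct
observation items carry a recording procedure — frequency, duration or
interval recording — that turns a raw :class:`EventLog` (onsets and
onset/offset intervals on a session clock) into a session score.  Interval
recording supports the three canonical applied-behavior-analysis sub-modes:
partial-interval, whole-interval and momentary time sampling.

Measures serialize to a versioned JSON schema so they can be exported,
shared and re-imported bit-exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any, Optional, Sequence, Union

SCHEMA_VERSION = 1

RECORDINGS = ("frequency", "duration", "interval")
INTERVAL_MODES = ("partial", "whole", "momentary")

__all__ = [
    "SCHEMA_VERSION",
    "DirectObservationItem",
    "ChoiceItem",
    "NumberItem",
    "RangeItem",
    "FourQuadrantItem",
    "TextItem",
    "Item",
    "Measure",
    "EventLog",
    "MeasureSchemaError",
    "ResponseValidationError",
    "summarize_frequency",
    "summarize_duration",
    "summarize_interval",
    "validate_response",
    "export_measure",
    "import_measure",
]


class MeasureSchemaError(ValueError):
    """Raised on malformed measure definitions; lists offending fields."""

    def __init__(self, fields: Sequence[str], message: str = "invalid measure"):
        self.fields = list(fields)
        super().__init__(f"{message}: {', '.join(self.fields)}")


class ResponseValidationError(ValueError):
    """Raised when a recorded response violates its item's constraints."""


@dataclass(frozen=True)
class DirectObservationItem:
    kind = "direct_observation"
    prompt: str
    recording: str = "frequency"
    interval_length: Optional[float] = None  # seconds, interval recording only
    interval_mode: str = "partial"

    def __post_init__(self) -> None:
        bad = []
        if self.recording not in RECORDINGS:
            bad.append("recording")
        if self.recording == "interval":
            if self.interval_length is None or self.interval_length <= 0:
                bad.append("interval_length")
            if self.interval_mode not in INTERVAL_MODES:
                bad.append("interval_mode")
        if bad:
            raise MeasureSchemaError(bad)


@dataclass(frozen=True)
class ChoiceItem:
    kind = "choice"
    prompt: str
    options: tuple[str, ...] = ()
    multiple_allowed: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "options", tuple(self.options))
        if len(self.options) < 2:
            raise MeasureSchemaError(["options"], "choice item needs >= 2 options")


@dataclass(frozen=True)
class NumberItem:
    kind = "number"
    prompt: str


@dataclass(frozen=True)
class RangeItem:
    kind = "range"
    prompt: str
    min: int = 0
    max: int = 50

    def __post_init__(self) -> None:
        if not self.min < self.max:
            raise MeasureSchemaError(["min", "max"], "range item needs min < max")


@dataclass(frozen=True)
class FourQuadrantItem:
    """Two crossed axes; a response is a point on the plane they span."""

    kind = "four_quadrant"
    prompt: str
    x_label: str = "x"
    y_label: str = "y"
    x_bounds: tuple[float, float] = (-1.0, 1.0)
    y_bounds: tuple[float, float] = (-1.0, 1.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "x_bounds", tuple(self.x_bounds))
        object.__setattr__(self, "y_bounds", tuple(self.y_bounds))
        bad = [
            name
            for name, (lo, hi) in (("x_bounds", self.x_bounds), ("y_bounds", self.y_bounds))
            if not lo < hi
        ]
        if bad:
            raise MeasureSchemaError(bad, "quadrant bounds need lo < hi")


@dataclass(frozen=True)
class TextItem:
    kind = "text"
    prompt: str


Item = Union[
    DirectObservationItem, ChoiceItem, NumberItem, RangeItem, FourQuadrantItem, TextItem
]

_ITEM_KINDS = {
    cls.kind: cls
    for cls in (
        DirectObservationItem,
        ChoiceItem,
        NumberItem,
        RangeItem,
        FourQuadrantItem,
        TextItem,
    )
}


@dataclass(frozen=True)
class Measure:
    name: str
    items: tuple[Item, ...]
    version: str = "1"

    def __post_init__(self) -> None:
        object.__setattr__(self, "items", tuple(self.items))
        if not self.items:
            raise MeasureSchemaError(["items"], "measure needs >= 1 item")
        prompts = [i.prompt for i in self.items]
        if len(set(prompts)) != len(prompts):
            raise MeasureSchemaError(["items"], "item prompts must be unique")


@dataclass(frozen=True)
class EventLog:
    """Raw behavior record on a session clock (seconds from session start).

    ``events`` holds instants (a float onset, or a ``(t, t)`` pair) and
    intervals (``(onset, offset)`` pairs).  All times lie in
    ``[0, duration]``.
    """

    duration: float
    events: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        norm = []
        for ev in self.events:
            if isinstance(ev, (int, float)):
                onset = offset = float(ev)
            else:
                onset, offset = float(ev[0]), float(ev[1])
            if not (0 <= onset <= offset <= self.duration):
                raise ValueError(
                    f"event ({onset}, {offset}) outside [0, {self.duration}]"
                )
            norm.append((onset, offset))
        object.__setattr__(self, "events", tuple(norm))

    def intervals(self) -> list[tuple[float, float]]:
        """Events with positive extent (instants excluded)."""
        return [(a, b) for a, b in self.events if b > a]


def _merged_intervals(log: EventLog) -> list[tuple[float, float]]:
    """Union of the log's intervals: overlaps merged, instants dropped."""
    ivs = sorted(log.intervals())
    merged: list[tuple[float, float]] = []
    for a, b in ivs:
        if merged and a <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return merged


def summarize_frequency(log: EventLog) -> int:
    """Number of behavior occurrences; instants and intervals count once each."""
    return len(log.events)


def summarize_duration(log: EventLog) -> float:
    """Total seconds of behavior: length of the union of the intervals.

    Overlapping intervals are merged first, so the result never exceeds the
    session duration and never double-counts time; instants contribute 0.
    """
    return sum(b - a for a, b in _merged_intervals(log))


def _bins(duration: float, interval_length: float) -> list[tuple[float, float]]:
    edges = []
    start = 0.0
    while start < duration:
        edges.append((start, min(start + interval_length, duration)))
        start += interval_length
    return edges or [(0.0, duration)]


def summarize_interval(log: EventLog, interval_length: float, mode: str = "partial") -> float:
    """Interval-recording score: proportion of bins scored, in [0, 1].

    The session is divided into bins of ``interval_length`` seconds (the
    last bin may be short).  ``partial``: a bin scores if any behavior
    touches it.  ``whole``: a bin scores only if behavior covers it
    entirely.  ``momentary``: a bin scores if behavior is occurring at the
    bin's endpoint (momentary time sampling).
    """
    if interval_length <= 0:
        raise ValueError("interval_length must be > 0")
    if mode not in INTERVAL_MODES:
        raise ValueError(f"unknown interval mode {mode!r}")
    bins = _bins(log.duration, interval_length)
    merged = _merged_intervals(log)
    instants = [a for a, b in log.events if a == b]
    hits = 0
    for lo, hi in bins:
        if mode == "partial":
            touched = any(a < hi and b > lo for a, b in merged) or any(
                lo <= t < hi or (hi == log.duration and t == hi) for t in instants
            )
            hits += touched
        elif mode == "whole":
            # covered iff the merged union contains [lo, hi]
            hits += any(a <= lo and b >= hi for a, b in merged)
        else:  # momentary: sample at the bin endpoint
            s = hi
            hits += any(a <= s <= b for a, b in log.events)
    return hits / len(bins)


def validate_response(item: Item, value: Any) -> Any:
    """Check a recorded response against its item's constraints.

    Returns the validated value; raises :class:`ResponseValidationError`
    on an out-of-range number, unknown choice option, or off-plane
    quadrant point.  Text responses pass through unchanged.
    """
    if isinstance(item, TextItem):
        return str(value)
    if isinstance(item, NumberItem):
        if not isinstance(value, (int, float)) or isinstance(value, bool):
            raise ResponseValidationError(f"{value!r} is not a number")
        return value
    if isinstance(item, RangeItem):
        if not isinstance(value, (int, float)) or isinstance(value, bool):
            raise ResponseValidationError(f"{value!r} is not a number")
        if not item.min <= value <= item.max:
            raise ResponseValidationError(
                f"{value} outside [{item.min}, {item.max}]"
            )
        return value
    if isinstance(item, ChoiceItem):
        values = value if item.multiple_allowed else [value]
        if item.multiple_allowed and not isinstance(value, (list, tuple, set)):
            raise ResponseValidationError("multiple-choice response must be a collection")
        for v in values:
            if v not in item.options:
                raise ResponseValidationError(f"unknown option {v!r}")
        return value
    if isinstance(item, FourQuadrantItem):
        try:
            x, y = value
        except (TypeError, ValueError) as exc:
            raise ResponseValidationError("quadrant response must be an (x, y) pair") from exc
        if not (item.x_bounds[0] <= x <= item.x_bounds[1]) or not (
            item.y_bounds[0] <= y <= item.y_bounds[1]
        ):
            raise ResponseValidationError(f"point ({x}, {y}) off the quadrant plane")
        return (x, y)
    if isinstance(item, DirectObservationItem):
        # a direct-observation "response" is an EventLog or a session score
        if isinstance(value, EventLog):
            return value
        if isinstance(value, int) and value >= 0:
            return value
        raise ResponseValidationError(
            "direct-observation response must be an EventLog or a non-negative count"
        )
    raise ResponseValidationError(f"unknown item type {type(item).__name__}")


def _item_to_dict(item: Item) -> dict:
    d: dict[str, Any] = {"kind": item.kind, "prompt": item.prompt}
    if isinstance(item, DirectObservationItem):
        d["recording"] = item.recording
        if item.recording == "interval":
            d["interval_length"] = item.interval_length
            d["interval_mode"] = item.interval_mode
    elif isinstance(item, ChoiceItem):
        d["options"] = list(item.options)
        d["multiple_allowed"] = item.multiple_allowed
    elif isinstance(item, RangeItem):
        d["min"] = item.min
        d["max"] = item.max
    elif isinstance(item, FourQuadrantItem):
        d["x_label"] = item.x_label
        d["y_label"] = item.y_label
        d["x_bounds"] = list(item.x_bounds)
        d["y_bounds"] = list(item.y_bounds)
    return d


def _item_from_dict(d: dict, where: str) -> Item:
    if "kind" not in d:
        raise MeasureSchemaError([f"{where}.kind"], "item missing 'kind'")
    kind = d["kind"]
    if kind not in _ITEM_KINDS:
        raise MeasureSchemaError([f"{where}.kind"], f"unknown item kind {kind!r}")
    if "prompt" not in d:
        raise MeasureSchemaError([f"{where}.prompt"], "item missing 'prompt'")
    cls = _ITEM_KINDS[kind]
    payload = {k: v for k, v in d.items() if k not in ("kind",)}
    if kind in ("choice",):
        payload["options"] = tuple(payload.get("options", ()))
    if kind == "four_quadrant":
        for key in ("x_bounds", "y_bounds"):
            if key in payload:
                payload[key] = tuple(payload[key])
    try:
        return cls(**payload)
    except TypeError as exc:
        raise MeasureSchemaError([where], f"bad fields for {kind} item ({exc})") from exc


def export_measure(measure: Measure) -> str:
    """Serialize a measure to its versioned JSON document."""
    doc = {
        "schema_version": SCHEMA_VERSION,
        "name": measure.name,
        "version": measure.version,
        "items": [_item_to_dict(i) for i in measure.items],
    }
    return json.dumps(doc, indent=2, sort_keys=True)


def import_measure(text: str) -> Measure:
    """Parse a measure JSON document; ``import(export(m)) == m``."""
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise MeasureSchemaError(["<document>"], f"not valid JSON ({exc})") from exc
    missing = [k for k in ("schema_version", "name", "items") if k not in doc]
    if missing:
        raise MeasureSchemaError(missing, "measure document missing fields")
    if doc["schema_version"] != SCHEMA_VERSION:
        raise MeasureSchemaError(
            ["schema_version"], f"unsupported schema version {doc['schema_version']!r}"
        )
    items = [
        _item_from_dict(d, f"items[{i}]") for i, d in enumerate(doc["items"])
    ]
    return Measure(name=doc["name"], items=tuple(items), version=doc.get("version", "1"))
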