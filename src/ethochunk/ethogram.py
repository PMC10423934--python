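"""Ethogram definitions and behavioral event annotations.

An *ethogram* is the catalogue of behaviors scored in an assay.  Two kinds
of behavior are distinguished:

``chunk_scored``
    Scored present/absent (binary) within each randomly sampled video
    chunk.  The default maternal-behavior ethogram contains nine of these.

``whole_video``
    Measured once per recording by watching the whole assay: the delay to
    initiate the first pup retrieval, the delay to complete retrieval of
    all pups (both in seconds, censored at a cutoff when the event never
    happens), and an ordinal 0-4 nest score.

Events are stored with times in seconds at millisecond precision.
Interval events are half-open ``[start_s, stop_s)`` so that abutting
events never double-count a boundary instant; point events carry
``stop_s == start_s``.  Frame indices are never stored -- they are derived
from ``round(t * fps)`` when needed, because frame rate may vary per
recording.
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import yaml

from ethochunk.errors import ParseError, ValidationError

CHUNK_SCORED = "chunk_scored"
WHOLE_VIDEO = "whole_video"
_KINDS = (CHUNK_SCORED, WHOLE_VIDEO)

INTERVAL = "interval"
POINT = "point"
_EVENT_TYPES = (INTERVAL, POINT)

#: Canonical behavior names used by the scoring engine and the simulator.
PUP_RETRIEVAL = "pup retrieval"
ALL_PUPS_RETRIEVED = "all pups retrieved and grouped"
ALL_PUPS_NESTED = "all pups nested"

_TIME_DECIMALS = 3  # millisecond precision in memory and on disk


def _round_time(t: float) -> float:
    return round(float(t), _TIME_DECIMALS)


@dataclass(frozen=True)
class Behavior:
    """One entry of an ethogram.

    Parameters
    ----------
    name
        Short unique label, e.g. ``"pup retrieval"``.
    kind
        ``"chunk_scored"`` (binary presence per chunk) or
        ``"whole_video"`` (one measure per recording).
    value_domain
        ``"binary"`` for chunk-scored behaviors; ``"seconds"`` or
        ``"ordinal_0_4"`` for whole-video measures.
    description
        Free text shown to scorers.
    """

    name: str
    kind: str
    value_domain: str = "binary"
    description: str = ""

    def __post_init__(self) -> None:
        if not self.name or not self.name.strip():
            raise ValidationError("behavior name must be non-empty")
        if self.kind not in _KINDS:
            raise ValidationError(
                f"unknown behavior kind {self.kind!r}; expected one of {_KINDS}"
            )
        if self.kind == CHUNK_SCORED and self.value_domain != "binary":
            raise ValidationError(
                f"chunk_scored behavior {self.name!r} must have binary value_domain, "
                f"got {self.value_domain!r}"
            )


@dataclass(frozen=True)
class Ethogram:
    """Ordered, duplicate-free collection of behaviors."""

    behaviors: tuple[Behavior, ...]

    def __post_init__(self) -> None:
        if not self.behaviors:
            raise ValidationError("ethogram must define at least one behavior")
        seen: set[str] = set()
        for b in self.behaviors:
            if b.name in seen:
                raise ValidationError(f"duplicate behavior name: {b.name!r}")
            seen.add(b.name)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(b.name for b in self.behaviors)

    @property
    def chunk_scored(self) -> tuple[Behavior, ...]:
        return tuple(b for b in self.behaviors if b.kind == CHUNK_SCORED)

    @property
    def whole_video(self) -> tuple[Behavior, ...]:
        return tuple(b for b in self.behaviors if b.kind == WHOLE_VIDEO)

    def __contains__(self, name: object) -> bool:
        return name in self.names

    def __len__(self) -> int:
        return len(self.behaviors)

    def __getitem__(self, name: str) -> Behavior:
        for b in self.behaviors:
            if b.name == name:
                return b
        raise KeyError(name)


# The default maternal-behavior ethogram: nine chunk-scored behaviors plus
# three whole-video measures, matching standard blinded maternal behavior
# testing in mouse dams.
_DEFAULT_BEHAVIORS: tuple[Behavior, ...] = (
    Behavior(ALL_PUPS_RETRIEVED, CHUNK_SCORED, "binary",
             "all pups have been carried back to the nest and grouped"),
    Behavior(ALL_PUPS_NESTED, CHUNK_SCORED, "binary",
             "all pups are gathered in the nest"),
    Behavior(PUP_RETRIEVAL, CHUNK_SCORED, "binary",
             "dam carries a displaced pup back to the nest"),
    Behavior("pup interaction", CHUNK_SCORED, "binary",
             "sniffing or anogenital licking of a pup"),
    Behavior("crouching over pups", CHUNK_SCORED, "binary",
             "dam crouches in nursing posture over pups"),
    Behavior("resting with pups", CHUNK_SCORED, "binary",
             "dam rests in contact with pups"),
    Behavior("nest building", CHUNK_SCORED, "binary",
             "dam manipulates nesting material"),
    Behavior("solo activity", CHUNK_SCORED, "binary",
             "dam active away from pups"),
    Behavior("solo rest", CHUNK_SCORED, "binary",
             "dam resting away from pups"),
    Behavior("delay to initiate first pup retrieval", WHOLE_VIDEO, "seconds",
             "latency from assay start to first retrieval, censored at cutoff"),
    Behavior("delay to complete pup retrieval", WHOLE_VIDEO, "seconds",
             "latency until all pups are retrieved and grouped"),
    Behavior("nest score at 30 min", WHOLE_VIDEO, "ordinal_0_4",
             "0 no nest attempted .. 4 excellent nest with high structured walls"),
)


def default_ethogram() -> Ethogram:
    """The built-in maternal-behavior ethogram (9 chunk-scored + 3 whole-video)."""
    return Ethogram(_DEFAULT_BEHAVIORS)


def load_ethogram(source: str | Path | None = None) -> Ethogram:
    """Load an ethogram from a JSON/YAML file or literal text.

    ``source`` may be a path to a config file, a YAML/JSON string listing
    ``{name, kind, value_domain, description}`` mappings, or ``None`` for
    the default maternal-behavior ethogram.  Declared order is preserved.
    """
    if source is None:
        return default_ethogram()
    text: str
    if isinstance(source, Path):
        text = source.read_text(encoding="utf-8")
    else:
        p = Path(source)
        try:
            is_file = p.is_file()
        except OSError:
            is_file = False
        text = p.read_text(encoding="utf-8") if is_file else str(source)
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:  # pragma: no cover - malformed text
        raise ParseError(f"could not parse ethogram config: {exc}") from exc
    if raw is None or raw == []:
        raise ValidationError("ethogram config defines zero behaviors")
    if not isinstance(raw, list):
        raise ParseError("ethogram config must be a list of behavior mappings")
    behaviors = []
    for i, entry in enumerate(raw):
        if not isinstance(entry, dict) or "name" not in entry or "kind" not in entry:
            raise ParseError(f"behavior entry {i} must be a mapping with name and kind")
        behaviors.append(Behavior(
            name=str(entry["name"]),
            kind=str(entry["kind"]),
            value_domain=str(entry.get("value_domain", "binary")),
            description=str(entry.get("description", "")),
        ))
    return Ethogram(tuple(behaviors))


@dataclass(frozen=True)
class BehaviorEvent:
    """One annotated event: an interval ``[start_s, stop_s)`` or a point.

    The constructor checks only types; semantic invariants (positive
    interval length, times within the recording, behavior known to the
    ethogram) are reported as data by :func:`validate_annotation_set` so
    that questionable files can be loaded and inspected.
    """

    video_id: str
    behavior: str
    event_type: str
    start_s: float
    stop_s: float

    def __post_init__(self) -> None:
        if self.event_type not in _EVENT_TYPES:
            raise ValidationError(
                f"unknown event_type {self.event_type!r}; expected one of {_EVENT_TYPES}"
            )
        object.__setattr__(self, "start_s", _round_time(self.start_s))
        object.__setattr__(self, "stop_s", _round_time(self.stop_s))

    @classmethod
    def interval(cls, video_id: str, behavior: str, start_s: float, stop_s: float) -> "BehaviorEvent":
        return cls(video_id, behavior, INTERVAL, start_s, stop_s)

    @classmethod
    def point(cls, video_id: str, behavior: str, at_s: float) -> "BehaviorEvent":
        return cls(video_id, behavior, POINT, at_s, at_s)


@dataclass
class AnnotationSet:
    """All annotations for one recording, plus video and subject metadata.

    ``fps`` is metadata only; nothing in the pipeline consumes pixel data.
    The subject block carries one animal per recording (``animal_id``,
    ``strain``, ``lactation_day``).
    """

    video_id: str
    duration_s: float
    fps: float
    events: list[BehaviorEvent] = field(default_factory=list)
    animal_id: str = ""
    strain: str = ""
    lactation_day: int | None = None
    annotator: str = ""

    def events_for(self, behavior: str) -> list[BehaviorEvent]:
        return [e for e in self.events if e.behavior == behavior]


@dataclass(frozen=True)
class Violation:
    """One invariant violation found in an annotation set."""

    event_index: int  # -1 for set-level problems
    rule: str
    message: str


def validate_annotation_set(annotations: AnnotationSet, ethogram: Ethogram) -> list[Violation]:
    """Check an annotation set against its governing ethogram.

    Returns an empty list iff every event references a known behavior,
    interval events have positive length, point events have
    ``stop_s == start_s``, and all times lie within ``[0, duration_s]``.
    Violations are returned as data, never raised; the result is
    independent of event order (each event is judged on its own).
    """
    out: list[Violation] = []
    for i, ev in enumerate(annotations.events):
        if ev.behavior not in ethogram:
            out.append(Violation(i, "unknown_behavior",
                                 f"event {i}: behavior {ev.behavior!r} not in ethogram"))
        if ev.event_type == INTERVAL and not ev.start_s < ev.stop_s:
            out.append(Violation(i, "degenerate_interval",
                                 f"event {i}: interval requires start_s < stop_s "
                                 f"(got {ev.start_s} >= {ev.stop_s})"))
        if ev.event_type == POINT and ev.stop_s != ev.start_s:
            out.append(Violation(i, "point_stop_mismatch",
                                 f"event {i}: point event requires stop_s == start_s"))
        if ev.start_s < 0 or ev.stop_s > annotations.duration_s or ev.stop_s < 0:
            out.append(Violation(i, "out_of_bounds",
                                 f"event {i}: times [{ev.start_s}, {ev.stop_s}] outside "
                                 f"[0, {annotations.duration_s}]"))
    return out


# ---------------------------------------------------------------------------
# CSV round-trip
#
# UTF-8 comma-separated text with '.' decimal mark.  Leading comment lines
# starting with '#' hold key=value metadata; then a column-header row
# video_id,behavior,event_type,start_s,stop_s and one row per event.
# ---------------------------------------------------------------------------

_COLUMNS = ("video_id", "behavior", "event_type", "start_s", "stop_s")
_META_KEYS = ("video_id", "duration_s", "fps", "animal_id", "strain",
              "lactation_day", "annotator")


def _fmt_time(t: float) -> str:
    return f"{t:.3f}"


def write_annotations_csv(annotations: AnnotationSet, path: str | Path) -> None:
    """Write one recording's annotations to CSV (see module docstring for schema)."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        fh.write(f"# video_id={annotations.video_id}\n")
        fh.write(f"# duration_s={_fmt_time(annotations.duration_s)}\n")
        fh.write(f"# fps={annotations.fps:g}\n")
        fh.write(f"# animal_id={annotations.animal_id}\n")
        fh.write(f"# strain={annotations.strain}\n")
        ld = "" if annotations.lactation_day is None else str(annotations.lactation_day)
        fh.write(f"# lactation_day={ld}\n")
        fh.write(f"# annotator={annotations.annotator}\n")
        writer = csv.writer(fh)
        writer.writerow(_COLUMNS)
        for ev in annotations.events:
            writer.writerow([ev.video_id, ev.behavior, ev.event_type,
                             _fmt_time(ev.start_s), _fmt_time(ev.stop_s)])


def read_annotations_csv(path: str | Path) -> AnnotationSet:
    """Read an annotation CSV back into an :class:`AnnotationSet`.

    Raises :class:`~ethochunk.errors.ParseError` citing the offending line
    on malformed rows, and on a missing required column.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    events: list[BehaviorEvent] = []
    with path.open("r", encoding="utf-8", newline="") as fh:
        lines = fh.read().splitlines()
    body_start = 0
    for lineno, line in enumerate(lines, start=1):
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
            body_start = lineno
        else:
            break
    for key in ("video_id", "duration_s", "fps"):
        if key not in meta:
            raise ParseError(f"{path}: missing required metadata key {key!r}")
    body_lines = lines[body_start:]
    if not body_lines:
        raise ParseError(f"{path}: missing column header row")
    reader = csv.reader(io.StringIO("\n".join(body_lines)))
    header = next(reader)
    missing = [c for c in _COLUMNS if c not in header]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    idx = {c: header.index(c) for c in _COLUMNS}
    for rowno, row in enumerate(reader, start=body_start + 2):
        if not row or all(not c.strip() for c in row):
            continue
        if len(row) < len(header):
            raise ParseError(f"{path}: line {rowno}: expected {len(header)} fields, got {len(row)}")
        try:
            start_s = float(row[idx["start_s"]])
            stop_s = float(row[idx["stop_s"]])
        except ValueError as exc:
            raise ParseError(f"{path}: line {rowno}: non-numeric time field: {exc}") from exc
        if not (math.isfinite(start_s) and math.isfinite(stop_s)):
            raise ParseError(f"{path}: line {rowno}: non-finite time field")
        try:
            events.append(BehaviorEvent(
                video_id=row[idx["video_id"]],
                behavior=row[idx["behavior"]],
                event_type=row[idx["event_type"]],
                start_s=start_s,
                stop_s=stop_s,
            ))
        except ValidationError as exc:
            raise ParseError(f"{path}: line {rowno}: {exc}") from exc
    try:
        duration_s = float(meta["duration_s"])
        fps = float(meta["fps"])
    except ValueError as exc:
        raise ParseError(f"{path}: malformed metadata header: {exc}") from exc
    ld_raw = meta.get("lactation_day", "")
    lactation_day = int(ld_raw) if ld_raw else None
    return AnnotationSet(
        video_id=meta["video_id"],
        duration_s=_round_time(duration_s),
        fps=fps,
        events=events,
        animal_id=meta.get("animal_id", ""),
        strain=meta.get("strain", ""),
        lactation_day=lactation_day,
        annotator=meta.get("annotator", ""),
    )
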