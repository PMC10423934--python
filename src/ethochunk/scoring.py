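"""Chunk-level presence/absence scoring and whole-video maternal measures.

Chunk scoring reduces an event stream to a binary matrix: a chunk-scored
behavior is marked present (1) in a chunk iff some interval event of that
behavior overlaps the chunk window ``[start, start + dur)`` with positive
measure, or some point event falls inside the half-open window.  Any
positive-measure overlap counts -- a brief retrieval crossing a chunk
boundary is present in that chunk, matching how a human scorer marks
brief behaviors.

Whole-video measures are computed from the complete event stream (never
from chunks): the delay to initiate the first pup retrieval (censored at
a cutoff, 300 s by default, when no retrieval happens before it), the
delay to complete retrieval of all pups (censored at the assay horizon,
1800 s by default), and the ordinal 0-4 nest score assigned by the
scorer at assay end.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from ethochunk.errors import ParseError, ValidationError
from ethochunk.ethogram import (
    ALL_PUPS_RETRIEVED,
    INTERVAL,
    POINT,
    PUP_RETRIEVAL,
    AnnotationSet,
    Ethogram,
)
from ethochunk.sampling import Chunk, SamplingPlan


@dataclass(frozen=True)
class ScoringConfig:
    """Scoring thresholds.

    ``cutoff_initiate_s`` censors the retrieval-initiation latency (a dam
    that has not started retrieving by the cutoff scores the cutoff value,
    flagged censored).  ``completion_horizon_s`` plays the same role for
    retrieval completion and defaults to the assay length.
    """

    cutoff_initiate_s: float = 300.0
    completion_horizon_s: float = 1800.0
    presence_rule: str = "any_overlap"

    def __post_init__(self) -> None:
        if self.cutoff_initiate_s > self.completion_horizon_s:
            raise ValidationError(
                "cutoff_initiate_s must not exceed completion_horizon_s"
            )
        if self.presence_rule != "any_overlap":
            raise ValidationError(
                f"unknown presence_rule {self.presence_rule!r}; only 'any_overlap' is defined"
            )


@dataclass(frozen=True)
class WholeVideoMeasures:
    """Per-recording maternal-behavior measures with censoring flags."""

    latency_initiate_s: float
    initiate_censored: bool
    latency_complete_s: float
    complete_censored: bool
    nest_score: int


@dataclass
class ScoreSheet:
    """Chunk x behavior binary matrix for one recording.

    ``frame`` holds one row per chunk with columns ``chunk_id``,
    ``start_s``, ``dur_s`` followed by one 0/1 column per chunk-scored
    behavior, in ethogram order.
    """

    video_id: str
    behaviors: tuple[str, ...]
    frame: pd.DataFrame

    def __len__(self) -> int:
        return len(self.frame)


def score_chunk(annotations: AnnotationSet, chunk: Chunk, ethogram: Ethogram,
                config: ScoringConfig | None = None) -> dict[str, int]:
    """Score every chunk-scored behavior as present (1) or absent (0) in a chunk.

    Presence means any positive-measure overlap of an interval event with
    the half-open chunk window, or a point event inside it.  Overlapping
    events of the same behavior act as their union, so splitting an
    interval into abutting sub-intervals never changes a score.
    """
    config = config or ScoringConfig()
    c_start = chunk.start_s
    c_stop = chunk.start_s + chunk.dur_s
    if c_start < 0 or c_stop > annotations.duration_s:
        raise ValidationError(
            f"chunk [{c_start}, {c_stop}) outside video [0, {annotations.duration_s}]"
        )
    scores = {b.name: 0 for b in ethogram.chunk_scored}
    for ev in annotations.events:
        if ev.behavior not in scores:
            continue
        if ev.event_type == INTERVAL:
            hit = max(ev.start_s, c_start) < min(ev.stop_s, c_stop)
        else:  # point
            hit = c_start <= ev.start_s < c_stop
        if hit:
            scores[ev.behavior] = 1
    return scores


def build_scoresheet(annotations: AnnotationSet, plan: SamplingPlan,
                     ethogram: Ethogram,
                     config: ScoringConfig | None = None) -> ScoreSheet:
    """Apply chunk scoring over a sampling plan, one row per chunk."""
    if plan.video_id != annotations.video_id:
        raise ValidationError(
            f"plan is for video {plan.video_id!r} but annotations are for "
            f"{annotations.video_id!r}"
        )
    behaviors = tuple(b.name for b in ethogram.chunk_scored)
    rows = []
    for chunk in plan.chunks:
        scores = score_chunk(annotations, chunk, ethogram, config)
        rows.append({"chunk_id": chunk.chunk_id, "start_s": chunk.start_s,
                     "dur_s": chunk.dur_s, **{b: scores[b] for b in behaviors}})
    frame = pd.DataFrame(rows, columns=["chunk_id", "start_s", "dur_s", *behaviors])
    return ScoreSheet(video_id=plan.video_id, behaviors=behaviors, frame=frame)


def tally(scoresheet: ScoreSheet, behavior: str) -> int:
    """Number of chunks (out of those scored) in which a behavior was present."""
    if behavior not in scoresheet.behaviors:
        raise ValidationError(
            f"behavior {behavior!r} is not a chunk-scored column of this score sheet"
        )
    return int(scoresheet.frame[behavior].sum())


def _earliest_start(annotations: AnnotationSet, behavior: str) -> float | None:
    starts = [ev.start_s for ev in annotations.events if ev.behavior == behavior]
    return min(starts) if starts else None


def latency_to_initiate(annotations: AnnotationSet,
                        config: ScoringConfig | None = None) -> tuple[float, bool]:
    """Latency to the first pup-retrieval event, censored at the cutoff.

    Returns ``(seconds, censored)``: the earliest start of any
    "pup retrieval" event when it precedes the cutoff, else the cutoff
    value with the censored flag set.
    """
    config = config or ScoringConfig()
    first = _earliest_start(annotations, PUP_RETRIEVAL)
    if first is None or first >= config.cutoff_initiate_s:
        return (config.cutoff_initiate_s, True)
    return (first, False)


def latency_to_complete(annotations: AnnotationSet,
                        config: ScoringConfig | None = None) -> tuple[float, bool]:
    """Latency until all pups are retrieved and grouped, censored at the horizon."""
    config = config or ScoringConfig()
    done = _earliest_start(annotations, ALL_PUPS_RETRIEVED)
    if done is not None:
        first = _earliest_start(annotations, PUP_RETRIEVAL)
        if first is not None and done < first:
            warnings.warn(
                f"completion at {done} s precedes first retrieval at {first} s "
                f"in {annotations.video_id!r}; using earliest completion as recorded",
                stacklevel=2,
            )
    if done is None or done >= config.completion_horizon_s:
        return (config.completion_horizon_s, True)
    return (done, False)


def validate_nest_score(value: object) -> int:
    """Accept an integer nest score in 0..4; anything else is an error."""
    if isinstance(value, bool) or not isinstance(value, (int, float)):
        raise ValidationError(f"nest score must be an integer 0..4, got {value!r}")
    if isinstance(value, float) and not value.is_integer():
        raise ValidationError(f"nest score must be an integer, got {value!r}")
    iv = int(value)
    if not 0 <= iv <= 4:
        raise ValidationError(f"nest score must be in 0..4, got {iv}")
    return iv


def whole_video_measures(annotations: AnnotationSet, nest_score: int,
                         config: ScoringConfig | None = None) -> WholeVideoMeasures:
    """Bundle the three whole-video measures for one recording."""
    config = config or ScoringConfig()
    init_s, init_c = latency_to_initiate(annotations, config)
    comp_s, comp_c = latency_to_complete(annotations, config)
    return WholeVideoMeasures(
        latency_initiate_s=init_s,
        initiate_censored=init_c,
        latency_complete_s=comp_s,
        complete_censored=comp_c,
        nest_score=validate_nest_score(nest_score),
    )


# ---------------------------------------------------------------------------
# CSV output
# ---------------------------------------------------------------------------

_MEASURE_COLUMNS = ("video_id", "animal_id", "strain", "lactation_day",
                    "latency_initiate_s", "initiate_censored",
                    "latency_complete_s", "complete_censored", "nest_score")


def write_scoresheet_csv(scoresheet: ScoreSheet, path: str | Path) -> None:
    frame = scoresheet.frame.copy()
    frame.insert(0, "video_id", scoresheet.video_id)
    frame["start_s"] = frame["start_s"].map(lambda v: f"{v:.3f}")
    frame["dur_s"] = frame["dur_s"].map(lambda v: f"{v:.3f}")
    frame.to_csv(path, index=False)


def read_scoresheet_csv(path: str | Path) -> ScoreSheet:
    frame = pd.read_csv(path)
    fixed = ["video_id", "chunk_id", "start_s", "dur_s"]
    missing = [c for c in fixed if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    behaviors = tuple(c for c in frame.columns if c not in fixed)
    bad = frame[list(behaviors)].isin([0, 1]).all().all() if behaviors else True
    if not bad:
        raise ParseError(f"{path}: behavior columns must contain only 0/1")
    video_ids = frame["video_id"].unique()
    if len(video_ids) != 1:
        raise ParseError(f"{path}: a score sheet holds exactly one video_id")
    return ScoreSheet(video_id=str(video_ids[0]), behaviors=behaviors,
                      frame=frame.drop(columns=["video_id"]))


def measures_row(annotations: AnnotationSet, measures: WholeVideoMeasures) -> dict:
    """One tidy row of whole-video measures plus subject metadata."""
    return {
        "video_id": annotations.video_id,
        "animal_id": annotations.animal_id,
        "strain": annotations.strain,
        "lactation_day": annotations.lactation_day,
        "latency_initiate_s": measures.latency_initiate_s,
        "initiate_censored": measures.initiate_censored,
        "latency_complete_s": measures.latency_complete_s,
        "complete_censored": measures.complete_censored,
        "nest_score": measures.nest_score,
    }


def write_measures_csv(rows: Iterable[dict], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=_MEASURE_COLUMNS)
        writer.writeheader()
        for row in rows:
            out = dict(row)
            for key in ("latency_initiate_s", "latency_complete_s"):
                out[key] = f"{float(out[key]):.3f}"
            for key in ("initiate_censored", "complete_censored"):
                out[key] = str(bool(out[key])).lower()
            writer.writerow({k: out.get(k, "") for k in _MEASURE_COLUMNS})


def read_measures_csv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = [c for c in _MEASURE_COLUMNS if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    for key in ("initiate_censored", "complete_censored"):
        if frame[key].dtype == object:
            frame[key] = frame[key].map({"true": True, "false": False})
    return frame
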