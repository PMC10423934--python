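"""Synthetic maternal-behavior event streams with known ground truth.

The generator emulates a 30-min pup-retrieval assay: pups are scattered
away from the nest at time 0 and the dam's annotated behavior unfolds as

1. a retrieval-initiation latency ``L`` drawn lognormal (strain-specific
   log-median and spread), unless a Bernoulli failure suppresses
   retrieval entirely for that session;
2. one "pup retrieval" interval per pup, separated by gamma-distributed
   gaps, each carry lasting a fixed few seconds;
3. from the completion time ``T`` (end of the last retrieval) to assay
   end, "all pups retrieved and grouped" and "all pups nested" state
   intervals, plus alternating pup-directed ("crouching over pups" /
   "resting with pups") and solo ("solo activity" / "solo rest") bouts
   with exponential durations;
4. sporadic "nest building" and "pup interaction" bouts throughout;
5. an ordinal 0-4 nest score drawn from a strain-specific categorical.

Each session's truth record stores the raw latency, completion time,
censoring flags (cutoff 300 s for initiation, assay end for completion),
and nest score, so pipeline output can be checked for exact agreement.
All event times are rounded to millisecond precision at generation time,
matching the annotation CSV schema, so CSV round-trips are lossless.

The two built-in parameter sets are invented fixtures tuned only for the
*direction* of the known strain contrast -- DBA/2J dams slower to
retrieve, failing more often, and building weaker nests than C57BL/6 --
never for any published magnitudes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from ethochunk.errors import ValidationError
from ethochunk.ethogram import (
    ALL_PUPS_NESTED,
    ALL_PUPS_RETRIEVED,
    PUP_RETRIEVAL,
    AnnotationSet,
    BehaviorEvent,
    write_annotations_csv,
)
from ethochunk.sampling import substream

_RETRIEVAL_DUR_S = 5.0      # seconds the dam spends carrying one pup
_NEST_BOUT_GAP_S = 400.0    # mean gap between nest-building bouts
_NEST_BOUT_DUR_S = 40.0     # mean nest-building bout duration
_INTERACT_GAP_S = 300.0     # mean gap between pup-interaction bouts
_INTERACT_DUR_S = 15.0      # mean pup-interaction bout duration

DEFAULT_CUTOFF_S = 300.0
DEFAULT_ASSAY_DUR_S = 1800.0


def _r(t: float) -> float:
    return round(float(t), 3)


@dataclass(frozen=True)
class StrainParams:
    """Generative parameters for one mouse strain.

    ``latency_log_median`` is the natural log of the median
    retrieval-initiation latency in seconds; ``latency_sigma`` the
    log-scale spread.  ``p_fail_retrieve`` is the probability a session
    shows no retrieval at all.  Inter-retrieval gaps are gamma
    distributed; post-completion pup-directed and solo bouts alternate
    with exponential mean durations ``bout_on_mean_s`` and
    ``bout_off_mean_s``.  ``nest_score_probs`` gives the categorical
    distribution over nest scores 0-4.
    """

    name: str
    latency_log_median: float
    latency_sigma: float
    p_fail_retrieve: float
    n_pups: int
    inter_retrieval_shape: float
    inter_retrieval_scale: float
    bout_on_mean_s: float
    bout_off_mean_s: float
    nest_score_probs: tuple[float, float, float, float, float]

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_fail_retrieve <= 1.0:
            raise ValidationError("p_fail_retrieve must lie in [0, 1]")
        if self.latency_sigma < 0:
            raise ValidationError("latency_sigma must be >= 0")
        if self.n_pups < 1:
            raise ValidationError("n_pups must be >= 1")
        for nm, v in (("inter_retrieval_shape", self.inter_retrieval_shape),
                      ("inter_retrieval_scale", self.inter_retrieval_scale),
                      ("bout_on_mean_s", self.bout_on_mean_s),
                      ("bout_off_mean_s", self.bout_off_mean_s)):
            if v <= 0:
                raise ValidationError(f"{nm} must be > 0")
        probs = self.nest_score_probs
        if len(probs) != 5 or any(p < 0 or p > 1 for p in probs):
            raise ValidationError("nest_score_probs must be 5 probabilities")
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ValidationError("nest_score_probs must sum to 1")

    @property
    def median_latency_s(self) -> float:
        return math.exp(self.latency_log_median)


#: Invented fixture parameters.  C57BL/6 dams: fast, reliable retrievers
#: and strong nest builders.  DBA/2J dams: slower to initiate, more
#: likely to fail retrieval outright, weaker nests.
C57BL6_PARAMS = StrainParams(
    name="C57BL/6",
    latency_log_median=math.log(45.0),
    latency_sigma=0.6,
    p_fail_retrieve=0.02,
    n_pups=3,
    inter_retrieval_shape=2.0,
    inter_retrieval_scale=15.0,
    bout_on_mean_s=90.0,
    bout_off_mean_s=45.0,
    nest_score_probs=(0.0, 0.05, 0.15, 0.40, 0.40),
)

DBA2J_PARAMS = StrainParams(
    name="DBA/2J",
    latency_log_median=math.log(200.0),
    latency_sigma=0.9,
    p_fail_retrieve=0.25,
    n_pups=3,
    inter_retrieval_shape=2.0,
    inter_retrieval_scale=40.0,
    bout_on_mean_s=45.0,
    bout_off_mean_s=90.0,
    nest_score_probs=(0.15, 0.35, 0.30, 0.15, 0.05),
)


def default_strain_params() -> dict[str, StrainParams]:
    return {p.name: p for p in (C57BL6_PARAMS, DBA2J_PARAMS)}


@dataclass(frozen=True)
class SimConfig:
    """Cohort layout: dams per strain, lactation days, assay length, seed."""

    n_per_strain: Mapping[str, int] = field(
        default_factory=lambda: {"C57BL/6": 5, "DBA/2J": 6})
    days: tuple[int, ...] = (1, 3, 5)
    assay_dur_s: float = DEFAULT_ASSAY_DUR_S
    seed: int = 0

    def __post_init__(self) -> None:
        if self.assay_dur_s <= 0:
            raise ValidationError("assay_dur_s must be > 0")
        for strain, n in self.n_per_strain.items():
            if n < 1:
                raise ValidationError(f"n_per_strain[{strain!r}] must be >= 1")
        if not self.days:
            raise ValidationError("at least one lactation day is required")


def _bouts(rng: np.random.Generator, t0: float, t_end: float,
           mean_gap: float, mean_dur: float) -> list[tuple[float, float]]:
    """Alternating gap/bout renewal process on [t0, t_end), clipped."""
    out = []
    t = t0 + rng.exponential(mean_gap)
    while t < t_end:
        stop = min(t + rng.exponential(mean_dur), t_end)
        if _r(stop) > _r(t):
            out.append((t, stop))
        t = stop + rng.exponential(mean_gap)
    return out


def simulate_dam(params: StrainParams,
                 assay_dur_s: float = DEFAULT_ASSAY_DUR_S,
                 seed: int = 0,
                 video_id: str = "sim-dam",
                 animal_id: str = "",
                 lactation_day: int | None = None,
                 cutoff_s: float = DEFAULT_CUTOFF_S,
                 rng: np.random.Generator | None = None,
                 ) -> tuple[AnnotationSet, dict]:
    """Simulate one dam's assay; returns the annotation set and its truth record.

    The truth record holds the raw latency (``inf`` when retrieval never
    happens), the completion time, the censored measures exactly as the
    scoring engine should recover them, and the nest score.
    """
    if rng is None:
        rng = substream(seed, "dam", video_id)
    events: list[BehaviorEvent] = []

    failed = bool(rng.random() < params.p_fail_retrieve)
    latency_raw = math.inf
    if not failed:
        latency_raw = _r(rng.lognormal(mean=params.latency_log_median,
                                       sigma=params.latency_sigma))

    # Retrieval sequence: one carry per pup with gamma gaps.
    completion: float | None = None
    if latency_raw < assay_dur_s:
        t = latency_raw
        last_stop = None
        complete = True
        for pup in range(params.n_pups):
            stop = _r(min(t + _RETRIEVAL_DUR_S, assay_dur_s))
            if stop <= t:
                complete = False
                break
            events.append(BehaviorEvent.interval(video_id, PUP_RETRIEVAL, t, stop))
            last_stop = stop
            if stop >= assay_dur_s:
                complete = pup == params.n_pups - 1 and stop < assay_dur_s
                break
            if pup < params.n_pups - 1:
                t = _r(stop + rng.gamma(params.inter_retrieval_shape,
                                        params.inter_retrieval_scale))
                if t >= assay_dur_s:
                    complete = False
                    break
        if complete and last_stop is not None and last_stop < assay_dur_s:
            completion = last_stop

    if completion is not None:
        events.append(BehaviorEvent.interval(
            video_id, ALL_PUPS_RETRIEVED, completion, assay_dur_s))
        events.append(BehaviorEvent.interval(
            video_id, ALL_PUPS_NESTED, completion, assay_dur_s))
        # Alternating pup-directed vs solo bouts after completion.
        t = completion
        pup_directed = True
        while t < assay_dur_s:
            mean = params.bout_on_mean_s if pup_directed else params.bout_off_mean_s
            stop = min(t + rng.exponential(mean), assay_dur_s)
            if _r(stop) > _r(t):
                if pup_directed:
                    name = str(rng.choice(["crouching over pups", "resting with pups"]))
                else:
                    name = str(rng.choice(["solo activity", "solo rest"]))
                events.append(BehaviorEvent.interval(video_id, name, _r(t), _r(stop)))
            t = stop
            pup_directed = not pup_directed
    else:
        # No completion: the dam drifts between solo bouts all session.
        for start, stop in _bouts(rng, 0.0, assay_dur_s, params.bout_off_mean_s,
                                  params.bout_off_mean_s):
            name = str(rng.choice(["solo activity", "solo rest"]))
            events.append(BehaviorEvent.interval(video_id, name, _r(start), _r(stop)))

    for start, stop in _bouts(rng, 0.0, assay_dur_s, _NEST_BOUT_GAP_S, _NEST_BOUT_DUR_S):
        events.append(BehaviorEvent.interval(video_id, "nest building", _r(start), _r(stop)))
    for start, stop in _bouts(rng, 0.0, assay_dur_s, _INTERACT_GAP_S, _INTERACT_DUR_S):
        events.append(BehaviorEvent.interval(video_id, "pup interaction", _r(start), _r(stop)))

    nest_score = int(rng.choice(5, p=np.asarray(params.nest_score_probs, dtype=float)))

    init_censored = failed or latency_raw >= cutoff_s
    latency_initiate = cutoff_s if init_censored else latency_raw
    complete_censored = completion is None or completion >= assay_dur_s
    latency_complete = assay_dur_s if complete_censored else completion

    annotations = AnnotationSet(
        video_id=video_id,
        duration_s=float(assay_dur_s),
        fps=30.0,
        events=sorted(events, key=lambda e: (e.start_s, e.stop_s, e.behavior)),
        animal_id=animal_id or video_id,
        strain=params.name,
        lactation_day=lactation_day,
        annotator="simulator",
    )
    truth = {
        "video_id": video_id,
        "animal_id": annotations.animal_id,
        "strain": params.name,
        "lactation_day": lactation_day,
        "failed_retrieval": failed,
        "latency_raw_s": latency_raw,
        "latency_initiate_s": float(latency_initiate),
        "initiate_censored": bool(init_censored),
        "completion_raw_s": math.inf if completion is None else completion,
        "latency_complete_s": float(latency_complete),
        "complete_censored": bool(complete_censored),
        "nest_score": nest_score,
    }
    return annotations, truth


def _slug(strain: str) -> str:
    return "".join(ch for ch in strain if ch.isalnum()).lower()


def simulate_cohort(config: SimConfig | None = None,
                    params_by_strain: Mapping[str, StrainParams] | None = None,
                    ) -> tuple[list[AnnotationSet], pd.DataFrame]:
    """Simulate a full cohort: every dam of every strain on every lactation day.

    Each session is independently seeded from
    ``(config.seed, strain, animal index, day)``, so enlarging the cohort
    never changes an existing session.  Returns the annotation sets and a
    tidy truth table (one row per session).
    """
    config = config or SimConfig()
    params_by_strain = params_by_strain or default_strain_params()
    for strain in config.n_per_strain:
        if strain not in params_by_strain:
            raise ValidationError(f"no StrainParams given for strain {strain!r}")
    sets: list[AnnotationSet] = []
    truth_rows: list[dict] = []
    for strain in sorted(config.n_per_strain):
        params = params_by_strain[strain]
        for animal in range(config.n_per_strain[strain]):
            animal_id = f"{_slug(strain)}-dam{animal:02d}"
            for day in config.days:
                video_id = f"{animal_id}-ld{day}"
                rng = substream(config.seed, "cohort", strain, animal, day)
                annotations, truth = simulate_dam(
                    params, assay_dur_s=config.assay_dur_s,
                    video_id=video_id, animal_id=animal_id,
                    lactation_day=day, rng=rng,
                )
                sets.append(annotations)
                truth_rows.append(truth)
    return sets, pd.DataFrame(truth_rows)


def write_cohort(sets: Sequence[AnnotationSet], truth: pd.DataFrame,
                 out_dir: str | Path) -> list[Path]:
    """Write per-dam annotation CSVs plus ``truth.csv`` under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for annotations in sets:
        path = out_dir / f"{annotations.video_id}.csv"
        write_annotations_csv(annotations, path)
        paths.append(path)
    truth_path = out_dir / "truth.csv"
    truth.to_csv(truth_path, index=False, float_format="%.3f")
    paths.append(truth_path)
    return paths


def censoring_probability(params: StrainParams,
                          cutoff_s: float = DEFAULT_CUTOFF_S) -> float:
    """Closed-form probability that a session's initiation latency is censored.

    ``P(censored) = p_fail + (1 - p_fail) * P(L >= cutoff)`` with ``L``
    lognormal.
    """
    if params.latency_sigma == 0:
        tail = 1.0 if params.median_latency_s >= cutoff_s else 0.0
    else:
        z = (math.log(cutoff_s) - params.latency_log_median) / params.latency_sigma
        tail = float(sps.norm.sf(z))
    return params.p_fail_retrieve + (1.0 - params.p_fail_retrieve) * tail


def recover_parameters(truth: pd.DataFrame, measures: pd.DataFrame,
                       expected_median_s: float | None = None) -> dict:
    """Compare pipeline output against the generator's truth records.

    ``measures`` is a whole-video measures table (columns as written by
    the scoring engine).  Reports exact agreement of latencies, censoring
    flags, and nest scores, plus the empirical median of the raw
    (uncensored) latencies against the generator's median when given.
    """
    merged = truth.merge(measures, on="video_id", suffixes=("_truth", "_pipe"))
    if len(merged) != len(truth):
        raise ValidationError("truth and measures tables do not cover the same sessions")
    uncensored = merged[~merged["initiate_censored_truth"].astype(bool)]
    report = {
        "n_sessions": int(len(merged)),
        "n_uncensored": int(len(uncensored)),
        "latency_initiate_match": float(
            (uncensored["latency_initiate_s_truth"]
             == uncensored["latency_initiate_s_pipe"]).mean()
        ) if len(uncensored) else 1.0,
        "initiate_censor_agreement": float(
            (merged["initiate_censored_truth"].astype(bool)
             == merged["initiate_censored_pipe"].astype(bool)).mean()),
        "latency_complete_match": float(
            (merged["latency_complete_s_truth"]
             == merged["latency_complete_s_pipe"]).mean()),
        "complete_censor_agreement": float(
            (merged["complete_censored_truth"].astype(bool)
             == merged["complete_censored_pipe"].astype(bool)).mean()),
        "nest_score_agreement": float(
            (merged["nest_score_truth"] == merged["nest_score_pipe"]).mean()),
        "censored_fraction": float(merged["initiate_censored_truth"].astype(bool).mean()),
    }
    raw = merged.loc[np.isfinite(merged["latency_raw_s"]), "latency_raw_s"]
    if len(raw):
        report["empirical_median_latency_s"] = float(raw.median())
        if expected_median_s is not None:
            report["expected_median_latency_s"] = float(expected_median_s)
            report["median_relative_error"] = float(
                abs(report["empirical_median_latency_s"] - expected_median_s)
                / expected_median_s)
    return report
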