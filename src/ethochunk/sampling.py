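"""Stratified randomized chunk sampling and blinded presentation schedules.

A long recording is first split into a small number of equal, contiguous
*pieces* (e.g. three 10-min pieces of a 30-min assay).  An equal number of
short fixed-duration *chunks* is then drawn uniformly at random, without
replacement, from within each piece.  Stratifying by piece prevents the
random draw from accidentally concentrating chunks at the start or end of
an assay, which matters for behaviors like pup retrieval that are far more
likely early in a session.  With the defaults (3 pieces x 10 chunks x
10 s) a 30-min recording is scored from only 5 min of video.

Chunks are drawn on an aligned slot grid: each piece is tiled with
``floor(piece_dur_s / chunk_dur_s)`` non-overlapping slots and a subset of
slots is selected.  This guarantees non-overlap by construction and makes
the uniformity of the draw directly testable.

For blinded scoring, chunks from any number of recordings are pooled and
presented in a uniformly random order under opaque blind codes, so the
scorer cannot infer animal, group, day, or the temporal context of a chunk
within its recording.  The code-to-chunk mapping (the *blind map*) is
written to a separate file that the scorer never sees.

All randomness is deterministic: each (recording, piece) pair gets its own
RNG substream derived by hashing ``(master_seed, video_id, piece_index)``
with BLAKE2b, so adding a recording to a dataset never perturbs another
recording's chunks.
"""

from __future__ import annotations

import csv
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from ethochunk.errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

#: Code alphabet without visually ambiguous characters (no 0/O, 1/I, 8/B).
_CODE_ALPHABET = "ACDEFGHJKLMNPQRSTUVWXYZ234567"
_CODE_LENGTH = 6


def substream(master_seed: int, *parts: object) -> np.random.Generator:
    """Deterministic RNG substream keyed by ``(master_seed, *parts)``.

    The key is hashed with BLAKE2b (8-byte digest, big-endian) so that
    streams for different keys are statistically independent and stable
    across platforms and Python versions.
    """
    h = hashlib.blake2b(digest_size=8)
    h.update(repr((int(master_seed),) + tuple(parts)).encode("utf-8"))
    return np.random.default_rng(int.from_bytes(h.digest(), "big"))


@dataclass(frozen=True)
class SamplingParams:
    """Parameters of the piece/chunk randomization.

    Defaults correspond to the standard 30-min maternal-behavior assay:
    3 pieces of 600 s, 10 chunks of 10 s per piece (300 s scored per
    recording).  Set ``pieces_n=1`` to disable stratification for assays
    whose behaviors are equally likely at any time.
    """

    pieces_n: int = 3
    piece_dur_s: float = 600.0
    chunks_per_piece: int = 10
    chunk_dur_s: float = 10.0
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.pieces_n < 1:
            raise ValidationError("pieces_n must be >= 1")
        if self.chunk_dur_s <= 0:
            raise ValidationError("chunk_dur_s must be > 0")
        if self.piece_dur_s <= 0:
            raise ValidationError("piece_dur_s must be > 0")
        if self.chunks_per_piece < 0:
            raise ValidationError("chunks_per_piece must be >= 0")
        if self.chunks_per_piece > self.slots_per_piece:
            raise ValidationError(
                f"chunks_per_piece={self.chunks_per_piece} exceeds the "
                f"{self.slots_per_piece} aligned slots per piece "
                f"(piece_dur_s={self.piece_dur_s}, chunk_dur_s={self.chunk_dur_s})"
            )

    @property
    def slots_per_piece(self) -> int:
        return int(self.piece_dur_s // self.chunk_dur_s)

    @property
    def scored_duration_s(self) -> float:
        """Total seconds of video scored per recording under this plan."""
        return self.pieces_n * self.chunks_per_piece * self.chunk_dur_s


@dataclass(frozen=True)
class Chunk:
    """One sampled sub-interval ``[start_s, start_s + dur_s)`` of a recording."""

    chunk_id: str
    video_id: str
    piece_index: int
    start_s: float
    dur_s: float

    @property
    def stop_s(self) -> float:
        return self.start_s + self.dur_s


@dataclass(frozen=True)
class SamplingPlan:
    """The chunk decomposition of one recording."""

    video_id: str
    chunks: tuple[Chunk, ...]
    params: SamplingParams | None = None

    def __post_init__(self) -> None:
        ids = [c.chunk_id for c in self.chunks]
        if len(set(ids)) != len(ids):
            raise ValidationError(f"duplicate chunk_id in plan for {self.video_id!r}")
        ordered = sorted(self.chunks, key=lambda c: c.start_s)
        for a, b in zip(ordered, ordered[1:]):
            if b.start_s < a.stop_s:
                raise ValidationError(
                    f"overlapping chunks in plan for {self.video_id!r}: "
                    f"{a.chunk_id} and {b.chunk_id}"
                )
        if self.params is not None:
            expected = self.params.pieces_n * self.params.chunks_per_piece
            if len(self.chunks) != expected:
                raise ValidationError(
                    f"plan for {self.video_id!r} has {len(self.chunks)} chunks, "
                    f"expected {expected}"
                )
            per_piece: dict[int, int] = {}
            for c in self.chunks:
                per_piece[c.piece_index] = per_piece.get(c.piece_index, 0) + 1
            for pi, n in per_piece.items():
                if n != self.params.chunks_per_piece:
                    raise ValidationError(
                        f"piece {pi} has {n} chunks, expected {self.params.chunks_per_piece}"
                    )

    @property
    def scored_duration_s(self) -> float:
        return sum(c.dur_s for c in self.chunks)


def partition_pieces(duration_s: float, params: SamplingParams) -> list[tuple[float, float]]:
    """Split ``[0, duration_s)`` into ``pieces_n`` contiguous half-open windows.

    The windows are anchored at 0 and each lasts ``piece_dur_s``.  Any
    trailing remainder beyond ``pieces_n * piece_dur_s`` is excluded from
    sampling with a logged warning (recordings often overrun slightly); a
    recording *shorter* than the required span is an error.
    """
    required = params.pieces_n * params.piece_dur_s
    if duration_s < required:
        raise ValidationError(
            f"duration {duration_s} s is too short: need at least {required} s "
            f"({params.pieces_n} pieces x {params.piece_dur_s} s)"
        )
    remainder = duration_s - required
    if remainder > 0:
        logger.warning(
            "excluding trailing %.3f s beyond the %d x %.0f s piece span",
            remainder, params.pieces_n, params.piece_dur_s,
        )
    return [
        (i * params.piece_dur_s, (i + 1) * params.piece_dur_s)
        for i in range(params.pieces_n)
    ]


def sample_chunks(video_id: str, duration_s: float, params: SamplingParams) -> SamplingPlan:
    """Draw a stratified random sampling plan for one recording.

    Within each piece, ``chunks_per_piece`` distinct aligned slots are
    drawn uniformly without replacement from the piece's slot grid, using
    the per-(recording, piece) RNG substream.  Identical inputs and seed
    reproduce the identical plan.
    """
    pieces = partition_pieces(duration_s, params)
    chunks: list[Chunk] = []
    for piece_index, (piece_start, _piece_stop) in enumerate(pieces):
        rng = substream(params.master_seed, video_id, piece_index)
        slots = rng.choice(params.slots_per_piece, size=params.chunks_per_piece,
                           replace=False)
        for slot in sorted(int(s) for s in slots):
            start = piece_start + slot * params.chunk_dur_s
            chunks.append(Chunk(
                chunk_id=f"p{piece_index}s{slot:03d}",
                video_id=video_id,
                piece_index=piece_index,
                start_s=float(start),
                dur_s=float(params.chunk_dur_s),
            ))
    return SamplingPlan(video_id=video_id, chunks=tuple(chunks), params=params)


@dataclass(frozen=True)
class ScheduleItem:
    """One scorer-facing presentation slot."""

    presentation_rank: int
    blind_code: str
    chunk_ref: tuple[str, str]  # (video_id, chunk_id); withheld from scorer files
    dur_s: float


@dataclass(frozen=True)
class PresentationSchedule:
    """Blinded, randomly ordered pooled chunks across recordings.

    ``items`` is a permutation of every chunk in the pooled plans, in
    presentation order.  ``blind_map`` inverts the opaque codes; it is
    written to a separate artifact so scorers never see it.
    """

    items: tuple[ScheduleItem, ...]
    blind_map: Mapping[str, Chunk]

    def __post_init__(self) -> None:
        ranks = [it.presentation_rank for it in self.items]
        if ranks != list(range(len(self.items))):
            raise ValidationError("presentation ranks must be 0..N-1 with no gaps")
        codes = [it.blind_code for it in self.items]
        if len(set(codes)) != len(codes):
            raise ValidationError("blind codes must be unique")

    def __len__(self) -> int:
        return len(self.items)


def _draw_blind_codes(rng: np.random.Generator, n: int) -> list[str]:
    """Draw ``n`` distinct fixed-length codes from a seeded code space."""
    codes: list[str] = []
    seen: set[str] = set()
    while len(codes) < n:
        letters = rng.integers(0, len(_CODE_ALPHABET), size=_CODE_LENGTH)
        code = "".join(_CODE_ALPHABET[int(i)] for i in letters)
        if code not in seen:
            seen.add(code)
            codes.append(code)
    return codes


def build_presentation(plans: Sequence[SamplingPlan], seed: int) -> PresentationSchedule:
    """Pool plans and emit a seeded uniformly random presentation order.

    Blind codes are opaque fixed-length strings carrying no information
    about recording, subject, or pooling order.
    """
    if not plans:
        raise ValidationError("need at least one sampling plan")
    pooled: list[Chunk] = []
    seen: set[tuple[str, str]] = set()
    for plan in plans:
        for chunk in plan.chunks:
            key = (chunk.video_id, chunk.chunk_id)
            if key in seen:
                raise ValidationError(f"duplicate chunk reference {key}")
            seen.add(key)
            pooled.append(chunk)
    rng = substream(seed, "presentation")
    order = rng.permutation(len(pooled))
    codes = _draw_blind_codes(substream(seed, "blind-codes"), len(pooled))
    items = []
    blind_map: dict[str, Chunk] = {}
    for rank, pooled_idx in enumerate(order):
        chunk = pooled[int(pooled_idx)]
        code = codes[rank]
        items.append(ScheduleItem(
            presentation_rank=rank,
            blind_code=code,
            chunk_ref=(chunk.video_id, chunk.chunk_id),
            dur_s=chunk.dur_s,
        ))
        blind_map[code] = chunk
    return PresentationSchedule(items=tuple(items), blind_map=blind_map)


def unblind(schedule: PresentationSchedule,
            scores: Mapping[str, object]) -> dict[tuple[str, str], object]:
    """Relabel a ``blind_code -> value`` table to ``(video_id, chunk_id) -> value``.

    The relabeling is a bijection: no score is lost or duplicated.
    Unknown blind codes raise an error listing every stale code.
    """
    unknown = sorted(code for code in scores if code not in schedule.blind_map)
    if unknown:
        raise ValidationError(f"unknown blind code(s): {unknown}")
    out: dict[tuple[str, str], object] = {}
    for code, value in scores.items():
        chunk = schedule.blind_map[code]
        out[(chunk.video_id, chunk.chunk_id)] = value
    return out


# ---------------------------------------------------------------------------
# File round-trip.  Plan CSV: video_id,chunk_id,piece_index,start_s,dur_s.
# Scorer-facing schedule CSV: presentation_rank,blind_code,dur_s -- it
# deliberately contains no column from which the recording, subject, or day
# could be recovered.  Blind map CSV: blind_code,video_id,chunk_id,start_s,dur_s.
# ---------------------------------------------------------------------------

_PLAN_COLUMNS = ("video_id", "chunk_id", "piece_index", "start_s", "dur_s")
_SCHEDULE_COLUMNS = ("presentation_rank", "blind_code", "dur_s")
_BLIND_MAP_COLUMNS = ("blind_code", "video_id", "chunk_id", "start_s", "dur_s")


def write_plan(plan: SamplingPlan, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_PLAN_COLUMNS)
        for c in plan.chunks:
            writer.writerow([c.video_id, c.chunk_id, c.piece_index,
                             f"{c.start_s:.3f}", f"{c.dur_s:.3f}"])


def read_plan(path: str | Path) -> SamplingPlan:
    path = Path(path)
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != list(_PLAN_COLUMNS):
            raise ParseError(f"{path}: expected header {','.join(_PLAN_COLUMNS)}")
        chunks = []
        video_id = None
        for rowno, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                chunk = Chunk(
                    chunk_id=row[1],
                    video_id=row[0],
                    piece_index=int(row[2]),
                    start_s=float(row[3]),
                    dur_s=float(row[4]),
                )
            except (IndexError, ValueError) as exc:
                raise ParseError(f"{path}: line {rowno}: {exc}") from exc
            if video_id is None:
                video_id = chunk.video_id
            elif chunk.video_id != video_id:
                raise ParseError(f"{path}: line {rowno}: mixed video_id in one plan file")
            chunks.append(chunk)
    if video_id is None:
        raise ParseError(f"{path}: plan file contains no chunks")
    return SamplingPlan(video_id=video_id, chunks=tuple(chunks))


def write_schedule(schedule: PresentationSchedule, schedule_path: str | Path,
                   blind_map_path: str | Path) -> None:
    """Write the scorer-facing schedule and the blind map as separate files."""
    with Path(schedule_path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_SCHEDULE_COLUMNS)
        for it in schedule.items:
            writer.writerow([it.presentation_rank, it.blind_code, f"{it.dur_s:.3f}"])
    with Path(blind_map_path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_BLIND_MAP_COLUMNS)
        for it in schedule.items:
            chunk = schedule.blind_map[it.blind_code]
            writer.writerow([it.blind_code, chunk.video_id, chunk.chunk_id,
                             f"{chunk.start_s:.3f}", f"{chunk.dur_s:.3f}"])


def read_schedule(schedule_path: str | Path, blind_map_path: str | Path,
                  plans: Sequence[SamplingPlan] | None = None) -> PresentationSchedule:
    """Reassemble a schedule from the scorer file plus the blind map.

    ``plans`` is optional; when given, piece indices are recovered from the
    matching plan chunks (the blind map alone stores no piece index).
    """
    by_ref: dict[tuple[str, str], Chunk] = {}
    if plans:
        for plan in plans:
            for c in plan.chunks:
                by_ref[(c.video_id, c.chunk_id)] = c
    blind_map: dict[str, Chunk] = {}
    bm_path = Path(blind_map_path)
    with bm_path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != list(_BLIND_MAP_COLUMNS):
            raise ParseError(f"{bm_path}: expected header {','.join(_BLIND_MAP_COLUMNS)}")
        for rowno, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                code, video_id, chunk_id = row[0], row[1], row[2]
                start_s, dur_s = float(row[3]), float(row[4])
            except (IndexError, ValueError) as exc:
                raise ParseError(f"{bm_path}: line {rowno}: {exc}") from exc
            known = by_ref.get((video_id, chunk_id))
            blind_map[code] = known if known is not None else Chunk(
                chunk_id=chunk_id, video_id=video_id, piece_index=-1,
                start_s=start_s, dur_s=dur_s,
            )
    items: list[ScheduleItem] = []
    sp = Path(schedule_path)
    with sp.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != list(_SCHEDULE_COLUMNS):
            raise ParseError(f"{sp}: expected header {','.join(_SCHEDULE_COLUMNS)}")
        for rowno, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                rank, code, dur_s = int(row[0]), row[1], float(row[2])
            except (IndexError, ValueError) as exc:
                raise ParseError(f"{sp}: line {rowno}: {exc}") from exc
            if code not in blind_map:
                raise ParseError(f"{sp}: line {rowno}: blind code {code!r} not in blind map")
            chunk = blind_map[code]
            items.append(ScheduleItem(
                presentation_rank=rank, blind_code=code,
                chunk_ref=(chunk.video_id, chunk.chunk_id), dur_s=dur_s,
            ))
    items.sort(key=lambda it: it.presentation_rank)
    return PresentationSchedule(items=tuple(items), blind_map=blind_map)
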