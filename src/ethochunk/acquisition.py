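"""Acquisition-side planning helpers and environment-log summaries.

These utilities cover the arithmetic done when provisioning a recording
rig and reviewing its environment logs: how many hours of video fit on a
drive, the segment windows of a repeated recording session, and
min/mean/max summaries of temperature and humidity over arbitrary time
windows.  Stable temperature and humidity inside an enclosed behavior box
matter because environmental disruptions confound behavior; the window
summaries let an analyst check, offline, whether a disruption occurred
during a given assay.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from ethochunk.errors import ParseError, ValidationError

_ENV_COLUMNS = ("timestamp", "temperature_c", "humidity_pct")
_CHANNELS = ("temperature_c", "humidity_pct")


def storage_capacity(drive_gb: float, file_gb: float, file_hours: float) -> float:
    """Hours of video a drive can hold, truncated to one decimal place.

    ``hours = file_hours * drive_gb / file_gb``.  Truncation (not
    rounding) is used so the figure is conservative: e.g. half-hour files
    of 3 GB on a 256 GB drive give 42.666... -> 42.6 h.
    """
    if file_gb <= 0:
        raise ValidationError("file_gb must be > 0")
    if file_hours <= 0:
        raise ValidationError("file_hours must be > 0")
    if drive_gb < 0:
        raise ValidationError("drive_gb must be >= 0")
    hours = file_hours * drive_gb / file_gb
    return math.floor(hours * 10.0) / 10.0


def recording_schedule(start_s: float, duration_s: float,
                       repeats: int) -> list[tuple[float, float]]:
    """Contiguous half-open recording windows: ``repeats`` segments of
    ``duration_s`` starting at ``start_s``."""
    if duration_s <= 0:
        raise ValidationError("duration_s must be > 0")
    if repeats < 1:
        raise ValidationError("repeats must be >= 1")
    return [
        (start_s + i * duration_s, start_s + (i + 1) * duration_s)
        for i in range(repeats)
    ]


@dataclass
class EnvLog:
    """Ordered temperature/humidity samples with strictly increasing timestamps."""

    samples: pd.DataFrame  # columns: timestamp (datetime64), temperature_c, humidity_pct

    def __post_init__(self) -> None:
        ts = self.samples["timestamp"]
        if len(ts) > 1 and not ts.is_monotonic_increasing:
            raise ParseError("environment log timestamps must be increasing")
        if len(ts) > 1 and ts.duplicated().any():
            raise ParseError("environment log timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.samples)


def parse_env_log(path: str | Path) -> EnvLog:
    """Read an environment log CSV (``timestamp,temperature_c,humidity_pct``,
    ISO-8601 timestamps)."""
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in _ENV_COLUMNS if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    try:
        frame["timestamp"] = pd.to_datetime(frame["timestamp"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise ParseError(f"{path}: unparseable timestamp: {exc}") from exc
    return EnvLog(samples=frame[list(_ENV_COLUMNS)])


def window_stats(log: EnvLog, t0, t1) -> dict:
    """Min/mean/max of each channel over samples with ``t0 <= timestamp < t1``.

    An empty window returns ``{"n": 0}`` with ``None`` per channel, never
    an exception.
    """
    t0 = pd.Timestamp(t0)
    t1 = pd.Timestamp(t1)
    if not t0 < t1:
        raise ValidationError("window requires t0 < t1")
    ts = log.samples["timestamp"]
    sub = log.samples[(ts >= t0) & (ts < t1)]
    out: dict = {"n": int(len(sub))}
    for channel in _CHANNELS:
        if len(sub) == 0:
            out[channel] = None
        else:
            vals = sub[channel].astype(float)
            out[channel] = {
                "min": float(vals.min()),
                "mean": float(vals.mean()),
                "max": float(vals.max()),
            }
    return out
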