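"""Preprocessing of raw context observations into engine-ready snapshots.

A raw observation is what the device-side providers deliver: an ISO
timestamp, an optional GPS/network position with the time of its last
fix, per-class activity probabilities on a 0-100 scale, and the battery
fraction.  Preprocessing adjusts the format for the fuzzy engine: the
altitude and the seconds in the timestamp are discarded, probabilities
are normalized to [0, 1], and the day-of-week / time-of-day coordinates
are computed.

Location fixes can go stale (no satellite visibility, poor network
coverage), so a snapshot carries the age of its fix and
:func:`location_confidence` converts that age into a multiplicative
confidence that linearly decays to zero over a configurable horizon
(default 27 minutes, the same span after which the scheduler declares
inference unavailable).  Stale location therefore lowers the degree of
activation rather than flipping it off.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from datetime import datetime
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from .fuzzy_core import ACTIVITY_CLASSES, day_week_value, time_of_day_value

__all__ = [
    "DEFAULT_STALE_HORIZON_S",
    "RawObservation",
    "ContextSnapshot",
    "MalformedRecordError",
    "preprocess",
    "location_confidence",
    "read_trace_csv",
    "write_trace_csv",
    "read_trace_jsonl",
    "write_trace_jsonl",
    "TRACE_COLUMNS",
]

#: Default staleness horizon: 27 min, aligned with the scheduler's
#: unavailability cutoff so that confidence is exhausted exactly when
#: inference would be declared stopped anyway.
DEFAULT_STALE_HORIZON_S: float = 27 * 60.0

TRACE_COLUMNS = ["timestamp", "lat", "lon", "alt", "fix_time", "battery"] + [
    f"p_{c}" for c in ACTIVITY_CLASSES
]


class MalformedRecordError(ValueError):
    """A trace record could not be parsed; carries the 1-based line number."""

    def __init__(self, line: int, reason: str):
        super().__init__(f"line {line}: {reason}")
        self.line = line
        self.reason = reason


class RawObservation(BaseModel):
    """One unprocessed context record as delivered by the providers."""

    timestamp: datetime
    latitude: Optional[float] = Field(default=None, ge=-90, le=90)
    longitude: Optional[float] = Field(default=None, ge=-180, le=180)
    altitude: Optional[float] = None
    activity: Optional[dict[str, float]] = None  # 0-100 scale per class
    battery: float = Field(ge=0.0, le=1.0)
    location_fix_time: Optional[datetime] = None

    @field_validator("activity")
    @classmethod
    def _check_activity(cls, v):
        if v is None:
            return v
        unknown = set(v) - set(ACTIVITY_CLASSES)
        if unknown:
            raise ValueError(f"unknown activity classes {sorted(unknown)}")
        for c, p in v.items():
            if not 0.0 <= p <= 100.0:
                raise ValueError(f"activity probability for {c!r} outside [0, 100]: {p}")
        return {c: float(v.get(c, 0.0)) for c in ACTIVITY_CLASSES}

    @model_validator(mode="after")
    def _check_position(self):
        if (self.latitude is None) != (self.longitude is None):
            raise ValueError("latitude and longitude must be given together")
        return self


@dataclass(frozen=True)
class ContextSnapshot:
    """A preprocessed observation ready for rule evaluation.

    ``position`` is ``(lat, lon)`` or ``None`` when no fix is available;
    ``fix_age_s`` is the age of the fix in seconds at evaluation time.
    Activity probabilities are normalized to [0, 1]; ``None`` when the
    recognition service produced nothing.
    """

    timestamp: datetime
    x_w: float
    x_t: float
    position: Optional[tuple[float, float]]
    fix_age_s: float
    activity: Optional[dict[str, float]]
    battery: float

    @property
    def has_location(self) -> bool:
        return self.position is not None

    @property
    def has_activity(self) -> bool:
        return self.activity is not None


def preprocess(raw: RawObservation, at: datetime | None = None) -> ContextSnapshot:
    """Format a raw observation for the engine.

    Drops the altitude, truncates timestamps to the minute, divides the
    0-100 activity probabilities by 100 and computes the day-of-week /
    time-of-day coordinates.  ``at`` is the evaluation time used to age
    the location fix (defaults to the observation's own timestamp, i.e.
    a fix is fresh when no explicit fix time is recorded).
    """
    ts = raw.timestamp
    ref = at if at is not None else ts
    if raw.location_fix_time is not None and raw.latitude is not None:
        fix_age = max(0.0, (ref - raw.location_fix_time).total_seconds())
    else:
        fix_age = max(0.0, (ref - ts).total_seconds())
    position = (raw.latitude, raw.longitude) if raw.latitude is not None else None
    activity = (
        {c: raw.activity.get(c, 0.0) / 100.0 for c in ACTIVITY_CLASSES}
        if raw.activity is not None
        else None
    )
    return ContextSnapshot(
        timestamp=ts.replace(second=0, microsecond=0),
        x_w=day_week_value(ts),
        x_t=time_of_day_value(ts),
        position=position,
        fix_age_s=fix_age,
        activity=activity,
        battery=raw.battery,
    )


def location_confidence(fix_age_s: float, horizon_s: float = DEFAULT_STALE_HORIZON_S) -> float:
    """Confidence in a location fix of the given age: linear decay to 0.

    Returns ``max(0, 1 - fix_age/horizon)``; multiplied into the
    location condition truth so a stale fix lowers a rule's degree of
    activation smoothly.
    """
    if fix_age_s < 0:
        raise ValueError("fix age must be non-negative")
    if horizon_s <= 0:
        raise ValueError("horizon must be positive")
    return max(0.0, 1.0 - fix_age_s / horizon_s)


# ---------------------------------------------------------------------------
# Trace I/O
# ---------------------------------------------------------------------------

def _row_to_observation(row: dict, line: int) -> RawObservation:
    def _get(key):
        v = row.get(key)
        if v is None:
            return None
        if isinstance(v, float) and math.isnan(v):
            return None
        if isinstance(v, str) and v.strip() == "":
            return None
        return v

    try:
        activity_vals = {c: _get(f"p_{c}") for c in ACTIVITY_CLASSES}
        has_any = any(v is not None for v in activity_vals.values())
        return RawObservation(
            timestamp=_get("timestamp"),
            latitude=_get("lat"),
            longitude=_get("lon"),
            altitude=_get("alt"),
            battery=_get("battery"),
            location_fix_time=_get("fix_time"),
            activity={c: float(v or 0.0) for c, v in activity_vals.items()} if has_any else None,
        )
    except Exception as exc:  # pydantic ValidationError, ValueError, ...
        raise MalformedRecordError(line, str(exc)) from exc


def read_trace_csv(path: str | Path, strict: bool = True) -> list[RawObservation]:
    """Read a context trace from CSV.

    With ``strict`` (default) a malformed line raises
    :class:`MalformedRecordError` carrying its line number; otherwise
    malformed lines are skipped.
    """
    df = pd.read_csv(path, dtype={"timestamp": str, "fix_time": str})
    out: list[RawObservation] = []
    for i, row in enumerate(df.to_dict("records")):
        try:
            out.append(_row_to_observation(row, line=i + 2))  # +1 header, 1-based
        except MalformedRecordError:
            if strict:
                raise
    return out


def write_trace_csv(observations: Iterable[RawObservation], path: str | Path) -> None:
    rows = []
    for o in observations:
        row = {
            "timestamp": o.timestamp.isoformat(),
            "lat": o.latitude,
            "lon": o.longitude,
            "alt": o.altitude,
            "fix_time": o.location_fix_time.isoformat() if o.location_fix_time else None,
            "battery": o.battery,
        }
        for c in ACTIVITY_CLASSES:
            row[f"p_{c}"] = None if o.activity is None else o.activity.get(c, 0.0)
        rows.append(row)
    pd.DataFrame(rows, columns=TRACE_COLUMNS).to_csv(path, index=False)


def read_trace_jsonl(path: str | Path, strict: bool = True) -> list[RawObservation]:
    out: list[RawObservation] = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            if not line.strip():
                continue
            try:
                out.append(RawObservation.model_validate(json.loads(line)))
            except Exception as exc:
                if strict:
                    raise MalformedRecordError(i + 1, str(exc)) from exc
    return out


def write_trace_jsonl(observations: Iterable[RawObservation], path: str | Path) -> None:
    with open(path, "w") as fh:
        for o in observations:
            fh.write(o.model_dump_json() + "\n")
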