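"""Survey data model and preprocessing.

Reads the four standard survey tables (detections, effort, site covariates,
sunrise/sunset calendar), enforces temporal independence of detections,
assigns climatological seasons, converts clock time to radians on the
24-h circle, and tallies sampling effort in camera-days.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

TWO_PI = 2.0 * math.pi

#: month -> season name; winter wraps the calendar-year boundary
_MONTH_SEASON = {
    12: "winter", 1: "winter", 2: "winter",
    3: "spring", 4: "spring", 5: "spring",
    6: "summer", 7: "summer", 8: "summer",
    9: "fall", 10: "fall", 11: "fall",
}

SEASON_NAMES = ("winter", "spring", "summer", "fall")

COVARIATE_COLUMNS = ["SC", "FC", "GC", "WA", "AL", "DP", "DR", "WT"]

DETECTIONS_COLUMNS = ["camera_id", "species", "timestamp"]
EFFORT_COLUMNS = ["camera_id", "date"]
SITES_COLUMNS = ["camera_id", "season"] + COVARIATE_COLUMNS
CALENDAR_COLUMNS = ["month", "sunrise", "sunset"]


@dataclass(frozen=True)
class SeasonLabel:
    """A climatological season with its year tag.

    Winter spans two calendar years (December of year Y through February of
    year Y+1) and is tagged ``"Y–Y+1"``; the other seasons carry their own
    calendar year.
    """

    name: str
    year_tag: str

    def __post_init__(self) -> None:
        if self.name not in SEASON_NAMES:
            raise ValueError(f"unknown season name {self.name!r}")

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.name} {self.year_tag}"


@dataclass(frozen=True)
class DetectionEvent:
    """One time-stamped species record at a camera."""

    camera_id: str
    species: str
    timestamp: datetime


@dataclass(frozen=True)
class IndependentDetection:
    """A detection retained by the temporal independence filter."""

    camera_id: str
    species: str
    timestamp: datetime
    season: SeasonLabel = field(compare=False)
    time_radians: float = field(compare=False)


def assign_season(d: date) -> SeasonLabel:
    """Map a calendar date to its season.

    December belongs to the winter tagged ``"Y–Y+1"``; January and February
    to the winter tagged ``"Y-1–Y"``.
    """
    name = _MONTH_SEASON[d.month]
    if name == "winter":
        if d.month == 12:
            tag = f"{d.year}–{d.year + 1}"
        else:
            tag = f"{d.year - 1}–{d.year}"
    else:
        tag = str(d.year)
    return SeasonLabel(name, tag)


def time_to_radians(ts: datetime) -> float:
    """Clock time as an angle: midnight -> 0, a full day -> 2π."""
    minutes = ts.hour * 60 + ts.minute + ts.second / 60.0
    return (TWO_PI * minutes / 1440.0) % TWO_PI


def radians_to_time(angle: float) -> tuple[int, int]:
    """Inverse of :func:`time_to_radians`, to the minute: (hour, minute)."""
    minutes = round((angle % TWO_PI) / TWO_PI * 1440.0) % 1440
    return divmod(minutes, 60)


def filter_independent(
    events: list[DetectionEvent], window: float = 30.0
) -> list[IndependentDetection]:
    """Enforce temporal independence within each camera × species stream.

    A record is retained iff it is the first of its stream or at least
    ``window`` minutes after the last *retained* record of the same stream
    (sliding-anchor rule). Records exactly ``window`` minutes apart are both
    retained (closed bound). Output is chronological.

    Parameters
    ----------
    events
        Raw detection events; need not be sorted.
    window
        Independence window in minutes (> 0); 30 is the camera-trap standard.
    """
    if window <= 0:
        raise ValueError("independence window must be positive")
    delta = timedelta(minutes=window)
    kept: list[IndependentDetection] = []
    last_kept: dict[tuple[str, str], datetime] = {}
    for ev in sorted(events, key=lambda e: (e.timestamp, e.camera_id, e.species)):
        key = (ev.camera_id, ev.species)
        anchor = last_kept.get(key)
        if anchor is None or ev.timestamp - anchor >= delta:
            last_kept[key] = ev.timestamp
            kept.append(
                IndependentDetection(
                    camera_id=ev.camera_id,
                    species=ev.species,
                    timestamp=ev.timestamp,
                    season=assign_season(ev.timestamp.date()),
                    time_radians=time_to_radians(ev.timestamp),
                )
            )
    return kept


def camera_days(
    effort: pd.DataFrame,
    camera_id: str | None = None,
    start: date | None = None,
    end: date | None = None,
) -> int:
    """Count active camera-days, optionally for one camera and/or a period.

    ``effort`` has one row per camera-day with columns ``camera_id`` and
    ``date``. ``start``/``end`` bound the period inclusively. Asking for a
    camera absent from the effort table is an error (a camera with zero
    effort in a *sub*-period of its deployment returns 0).
    """
    df = effort
    if camera_id is not None:
        if camera_id not in set(df["camera_id"]):
            raise KeyError(f"camera {camera_id!r} absent from effort table")
        df = df[df["camera_id"] == camera_id]
    dates = pd.to_datetime(df["date"]).dt.date
    mask = pd.Series(True, index=df.index)
    if start is not None:
        mask &= dates >= start
    if end is not None:
        mask &= dates <= end
    return int(mask.sum())


def season_date_range(season: SeasonLabel) -> tuple[date, date]:
    """Inclusive first and last calendar date of a season."""
    if season.name == "winter":
        y0 = int(season.year_tag.split("–")[0])
        start = date(y0, 12, 1)
        end = date(y0 + 1, 3, 1) - timedelta(days=1)
    else:
        y = int(season.year_tag)
        first_month = {"spring": 3, "summer": 6, "fall": 9}[season.name]
        start = date(y, first_month, 1)
        last_month = first_month + 2
        end = date(y, last_month + 1, 1) - timedelta(days=1) if last_month < 12 \
            else date(y, 12, 31)
    return start, end


# ---------------------------------------------------------------------------
# CSV readers with strict header validation


def _validate_headers(df: pd.DataFrame, required: list[str], path: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")


def read_detections(
    path: str | Path,
    known_cameras: set[str] | None = None,
    burn_in_end: date | None = None,
) -> list[DetectionEvent]:
    """Load detections.csv (camera_id, species, ISO-8601 timestamp).

    Malformed timestamps are rejected row by row (logged with line numbers);
    an unknown camera id is a hard error. ``burn_in_end`` drops all events
    up to and including that date (acclimation-period exclusion).
    """
    df = pd.read_csv(path, dtype=str)
    _validate_headers(df, DETECTIONS_COLUMNS, str(path))
    ts = pd.to_datetime(df["timestamp"], errors="coerce")
    bad = ts.isna()
    for idx in df.index[bad]:
        # +2: header line plus 1-based indexing
        logger.warning("%s: line %d: unparseable timestamp %r — row rejected",
                       path, idx + 2, df.at[idx, "timestamp"])
    df = df[~bad]
    ts = ts[~bad]
    if known_cameras is not None:
        unknown = set(df["camera_id"]) - known_cameras
        if unknown:
            raise ValueError(f"{path}: unknown camera id(s) {sorted(unknown)}")
    events = [
        DetectionEvent(cam, sp, t.to_pydatetime())
        for cam, sp, t in zip(df["camera_id"], df["species"], ts)
    ]
    if burn_in_end is not None:
        events = [e for e in events if e.timestamp.date() > burn_in_end]
    return events


def read_effort(path: str | Path) -> pd.DataFrame:
    """Load effort.csv (camera_id, date): one row per active camera-day."""
    df = pd.read_csv(path, dtype={"camera_id": str})
    _validate_headers(df, EFFORT_COLUMNS, str(path))
    df["date"] = pd.to_datetime(df["date"]).dt.date
    if df.duplicated(["camera_id", "date"]).any():
        raise ValueError(f"{path}: duplicate camera-day rows")
    return df


def read_sites(path: str | Path) -> pd.DataFrame:
    """Load sites.csv: per-camera, per-season habitat covariates.

    Covariates: % shrub (SC), forb (FC) and grass (GC) cover; distance to
    wadi (WA), guardhouse/marabout (DP), dirt road (DR) and water trough
    (WT), all in metres; altitude (AL) in m a.s.l.
    """
    df = pd.read_csv(path, dtype={"camera_id": str, "season": str})
    _validate_headers(df, SITES_COLUMNS, str(path))
    for col in ("SC", "FC", "GC"):
        vals = df[col].astype(float)
        if ((vals < 0) | (vals > 100)).any():
            raise ValueError(f"{path}: column {col} outside [0, 100]")
    for col in ("WA", "AL", "DP", "DR", "WT"):
        if (df[col].astype(float) < 0).any():
            raise ValueError(f"{path}: column {col} has negative values")
    return df


def read_calendar(path: str | Path) -> pd.DataFrame:
    """Load calendar.csv: month (1-12), mean sunrise and sunset (HH:MM)."""
    df = pd.read_csv(path, dtype={"sunrise": str, "sunset": str})
    _validate_headers(df, CALENDAR_COLUMNS, str(path))
    for col in ("sunrise", "sunset"):
        df[col] = df[col].map(_parse_hhmm)
    if not (df["sunrise"] < df["sunset"]).all():
        raise ValueError(f"{path}: sunrise must precede sunset in every month")
    return df


def _parse_hhmm(text: str) -> float:
    """'HH:MM' -> fractional hours."""
    h, m = text.strip().split(":")
    hours = int(h) + int(m) / 60.0
    if not 0 <= hours < 24:
        raise ValueError(f"time of day out of range: {text!r}")
    return hours
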