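"""Parsing, filtering and half-daily partitioning of active-fire detections.

Detection records follow the monthly VIIRS I-band fire-location product
layout: one row per thermal anomaly with latitude, longitude, fire radiative
power (MW), UTC acquisition date and time, an anomaly-type code (0 = presumed
vegetation fire) and a confidence class (low / nominal / high).  The exact
column header varies between product versions, so the parser takes a
configurable column map.
"""

from __future__ import annotations

import datetime as _dt
import enum
import functools
import logging
from dataclasses import dataclass, field

import pandas as pd
from shapely.geometry import Point
from shapely.geometry.base import BaseGeometry
from shapely.prepared import prep

logger = logging.getLogger(__name__)


class Confidence(enum.Enum):
    LOW = "low"
    NOMINAL = "nominal"
    HIGH = "high"

    @classmethod
    def parse(cls, value) -> "Confidence":
        s = str(value).strip().lower()
        aliases = {"l": cls.LOW, "n": cls.NOMINAL, "h": cls.HIGH}
        if s in aliases:
            return aliases[s]
        return cls(s)


@functools.total_ordering
@dataclass(frozen=True)
class TimeStep:
    """Half-daily time index: a calendar day plus an AM or PM half.

    The successor of (d, AM) is (d, PM); the successor of (d, PM) is
    (d+1, AM).  The AM half covers local times [00:00, 12:00) and the PM
    half [12:00, 24:00), a symmetric split around the ~01:30/13:30
    satellite overpasses.
    """

    date: _dt.date
    half: str  # "AM" | "PM"

    def __post_init__(self):
        if self.half not in ("AM", "PM"):
            raise ValueError(f"half must be 'AM' or 'PM', got {self.half!r}")

    @property
    def index(self) -> int:
        """Monotone integer index; consecutive steps differ by 1."""
        return self.date.toordinal() * 2 + (0 if self.half == "AM" else 1)

    def __lt__(self, other: "TimeStep") -> bool:
        return self.index < other.index

    def next(self) -> "TimeStep":
        if self.half == "AM":
            return TimeStep(self.date, "PM")
        return TimeStep(self.date + _dt.timedelta(days=1), "AM")

    def diff_days(self, other: "TimeStep") -> float:
        """Signed difference self - other, in days (half-steps are 0.5 d)."""
        return (self.index - other.index) / 2.0

    @classmethod
    def from_string(cls, s: str) -> "TimeStep":
        """Parse 'YYYYMMDDAM' / 'YYYYMMDDPM' (bare 'YYYYMMDD' means AM)."""
        s = s.strip().upper()
        half = "AM"
        if s.endswith(("AM", "PM")):
            half = s[-2:]
            s = s[:-2]
        return cls(_dt.datetime.strptime(s, "%Y%m%d").date(), half)

    def __str__(self) -> str:
        return self.date.strftime("%Y%m%d") + self.half


@dataclass(frozen=True)
class PixelRecord:
    """One active-fire detection."""

    lat: float
    lon: float
    frp: float  # MW
    acq_datetime: _dt.datetime  # UTC
    anomaly_type: int
    confidence: Confidence

    def __post_init__(self):
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude out of range: {self.lat}")
        if not -180.0 <= self.lon <= 180.0:
            raise ValueError(f"longitude out of range: {self.lon}")
        if not self.frp >= 0.0:
            raise ValueError(f"FRP must be >= 0, got {self.frp}")

    def local_datetime(self, utc_offset_hours: float) -> _dt.datetime:
        return self.acq_datetime + _dt.timedelta(hours=utc_offset_hours)

    def timestep(self, utc_offset_hours: float) -> TimeStep:
        """The half-daily step this detection falls in (local solar time)."""
        local = self.local_datetime(utc_offset_hours)
        return TimeStep(local.date(), "AM" if local.hour < 12 else "PM")


@dataclass
class ColumnMap:
    """Names of the required columns in a detection table."""

    lat: str = "lat"
    lon: str = "lon"
    frp: str = "frp"
    acq_date: str = "acq_date"  # YYYY-MM-DD or YYYYMMDD
    acq_time: str = "acq_time"  # HHMM or HH:MM (UTC)
    anomaly_type: str = "type"
    confidence: str = "confidence"

    def required(self) -> list[str]:
        return [self.lat, self.lon, self.frp, self.acq_date, self.acq_time,
                self.anomaly_type, self.confidence]


class FormatError(ValueError):
    """The detection file does not have the required columns."""


def _parse_datetime(date_val, time_val) -> _dt.datetime:
    ds = str(date_val).strip().replace("-", "").replace("/", "")
    d = _dt.datetime.strptime(ds, "%Y%m%d").date()
    ts = str(time_val).strip().replace(":", "")
    ts = ts.zfill(4)
    t = _dt.time(int(ts[:2]), int(ts[2:4]))
    return _dt.datetime.combine(d, t)


def parse_records(path, columns: ColumnMap | None = None) -> list[PixelRecord]:
    """Read a delimited detection table into a list of :class:`PixelRecord`.

    Rows that violate the record invariants (latitude/longitude out of
    range, negative FRP, unparseable fields) are dropped; the number of
    rejected rows is logged at WARNING level.

    Raises
    ------
    FormatError
        If a required column is missing from the header.
    """
    columns = columns or ColumnMap()
    df = pd.read_csv(path)
    missing = [c for c in columns.required() if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {missing}")

    records: list[PixelRecord] = []
    n_bad = 0
    for row in df.itertuples(index=False):
        row = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        try:
            rec = PixelRecord(
                lat=float(row[columns.lat]),
                lon=float(row[columns.lon]),
                frp=float(row[columns.frp]),
                acq_datetime=_parse_datetime(row[columns.acq_date], row[columns.acq_time]),
                anomaly_type=int(row[columns.anomaly_type]),
                confidence=Confidence.parse(row[columns.confidence]),
            )
        except (ValueError, KeyError, TypeError):
            n_bad += 1
            continue
        records.append(rec)
    if n_bad:
        logger.warning("parse_records: rejected %d malformed row(s) from %s", n_bad, path)
    return records


def filter_records(
    records: list[PixelRecord],
    roi: BaseGeometry,
    step: TimeStep,
    mode: str = "archive",
    utc_offset_hours: float = -8.0,
) -> list[PixelRecord]:
    """Select vegetation-fire detections inside ``roi`` during ``step``.

    Keeps records with anomaly type 0 (presumed vegetation fire) whose
    location falls inside the region polygon (boundary inclusive) and whose
    local acquisition time falls in the step's half-day window.  In ``nrt``
    mode — emulating the less quality-assured near-real-time product — only
    nominal- or high-confidence detections are kept.

    Idempotent: filtering an already-filtered batch is a no-op.
    """
    if mode not in ("archive", "nrt"):
        raise ValueError(f"mode must be 'archive' or 'nrt', got {mode!r}")
    if roi.is_empty or not roi.is_valid:
        raise ValueError("roi must be a valid, non-empty polygon")
    proi = prep(roi)
    out = []
    for r in records:
        if r.anomaly_type != 0:
            continue
        if mode == "nrt" and r.confidence is Confidence.LOW:
            continue
        if r.timestep(utc_offset_hours) != step:
            continue
        if not proi.covers(Point(r.lon, r.lat)):
            continue
        out.append(r)
    return out


def step_sequence(start: TimeStep, end: TimeStep) -> list[TimeStep]:
    """All half-daily steps from ``start`` to ``end`` inclusive, in order."""
    if start > end:
        raise ValueError(f"start step {start} is after end step {end}")
    steps = [start]
    while steps[-1] < end:
        steps.append(steps[-1].next())
    return steps


def partition_records(
    records: list[PixelRecord],
    steps: list[TimeStep],
    roi: BaseGeometry,
    mode: str = "archive",
    utc_offset_hours: float = -8.0,
) -> dict[TimeStep, list[PixelRecord]]:
    """Batch records by step; each passing record lands in exactly one batch."""
    return {
        s: filter_records(records, roi, s, mode=mode, utc_offset_hours=utc_offset_hours)
        for s in steps
    }
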