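"""Readers, writers and domain containers for the three study input dialects.

Three kinds of input feed the pipeline:

* minute-epoch actigraphy count series (one CSV per participant),
* per-night sleep-diary records,
* a per-participant clinical table joined to the survival outcome.

Readers validate and never impute: a missing value stays missing (``NaN`` /
``None``) and imputation is the job of :mod:`restwatch.feature_assembly`.
All timestamps are naive local time; the analysis is within-participant so no
timezone arithmetic is performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import (
    EmptySeries,
    MalformedEpochFile,
    SchemaError,
    UnparseableTime,
)

EPOCH_SECONDS = 60

DIARY_COLUMNS = [
    "participant_id",
    "night_index",
    "bed_time",
    "time_tried_sleep",
    "sol_min",
    "waso_min",
    "n_awakenings",
    "final_awakening",
    "get_up_time",
]


# ---------------------------------------------------------------------------
# clock-time helpers
# ---------------------------------------------------------------------------

def parse_clock(text) -> Optional[float]:
    """Parse ``HH:MM`` into minutes since midnight, ``None`` for blank cells."""
    if text is None or (isinstance(text, float) and np.isnan(text)):
        return None
    s = str(text).strip()
    if s == "" or s.lower() == "nan":
        return None
    parts = s.split(":")
    if len(parts) != 2:
        raise UnparseableTime(f"expected HH:MM, got {text!r}")
    try:
        hh, mm = int(parts[0]), int(parts[1])
    except ValueError as exc:
        raise UnparseableTime(f"expected HH:MM, got {text!r}") from exc
    if not (0 <= hh < 24 and 0 <= mm < 60):
        raise UnparseableTime(f"clock time out of range: {text!r}")
    return float(hh * 60 + mm)


def format_clock(minutes: Optional[float]) -> str:
    if minutes is None or (isinstance(minutes, float) and np.isnan(minutes)):
        return ""
    m = int(round(minutes)) % (24 * 60)
    return f"{m // 60:02d}:{m % 60:02d}"


def to_axis_minutes(minutes_since_midnight: float) -> float:
    """Map a clock time onto the 12:00->36:00 axis used throughout.

    Times before noon are shifted by +24 h so that bedtimes spanning midnight
    order correctly (23:00 < 00:30 becomes 1380 < 1470).
    """
    m = float(minutes_since_midnight)
    return m + 24 * 60 if m < 12 * 60 else m


def to_axis_hours(minutes_since_midnight: float) -> float:
    """Clock time as decimal hours on the 12->36 axis (07:30 -> 31.5)."""
    return to_axis_minutes(minutes_since_midnight) / 60.0


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class EpochSeries:
    """Gap-free 1-min epoch activity counts for one participant.

    ``counts`` is a float array where ``NaN`` marks a missing epoch (off-wrist
    or a filled recording gap).  Zero is a valid activity count and is never
    used as a missing marker.
    """

    participant_id: str
    start_time: pd.Timestamp
    counts: np.ndarray
    epoch_seconds: int = EPOCH_SECONDS

    def __post_init__(self):
        self.start_time = pd.Timestamp(self.start_time)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 1 or len(self.counts) < 1:
            raise EmptySeries(f"{self.participant_id}: empty epoch series")
        if self.epoch_seconds != EPOCH_SECONDS:
            raise MalformedEpochFile(
                f"epoch length must be {EPOCH_SECONDS}s, got {self.epoch_seconds}"
            )
        finite = self.counts[~np.isnan(self.counts)]
        if np.any(finite < 0):
            raise MalformedEpochFile("negative activity counts")

    def __len__(self) -> int:
        return len(self.counts)

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start_time, periods=len(self.counts), freq="60s")

    @property
    def end_time(self) -> pd.Timestamp:
        return self.start_time + pd.Timedelta(seconds=EPOCH_SECONDS * len(self.counts))

    def index_of(self, when: pd.Timestamp) -> int:
        """Epoch index containing ``when`` (exact 60-s grid assumed)."""
        delta = (pd.Timestamp(when) - self.start_time).total_seconds()
        return int(delta // EPOCH_SECONDS)

    @property
    def n_days(self) -> float:
        return len(self.counts) / 1440.0


@dataclass
class BedSchedule:
    """Per-night in-bed intervals (from event markers or the sleep diary)."""

    participant_id: str
    intervals: list  # list[(pd.Timestamp in_bed_start, pd.Timestamp out_of_bed_end)]

    def __post_init__(self):
        ivs = [(pd.Timestamp(a), pd.Timestamp(b)) for a, b in self.intervals]
        for a, b in ivs:
            dur_h = (b - a).total_seconds() / 3600.0
            if not (0.0 < dur_h < 24.0):
                raise SchemaError(f"in-bed interval duration {dur_h:.2f} h out of (0, 24)")
        for (a0, b0), (a1, b1) in zip(ivs, ivs[1:]):
            if a1 < b0:
                raise SchemaError("in-bed intervals overlap or are unordered")
        self.intervals = ivs

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass
class DiaryNight:
    """One night of the consensus sleep diary; ``None`` marks a missing cell."""

    participant_id: str
    night_index: int
    bed_time: Optional[float]  # minutes since midnight
    time_tried_sleep: Optional[float]
    sol_min: Optional[float]
    waso_min: Optional[float]
    n_awakenings: Optional[float]
    final_awakening: Optional[float]
    get_up_time: Optional[float]

    def __post_init__(self):
        for name in ("sol_min", "waso_min", "n_awakenings"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise SchemaError(f"{name} must be >= 0, got {v}")


@dataclass
class ClinicalRecord:
    """Raw clinical predictor fields plus the survival outcome."""

    participant_id: str
    values: dict
    survival_days: float
    event: int

    def __post_init__(self):
        if self.survival_days < 0:
            raise SchemaError(f"{self.participant_id}: negative survival time")
        if self.event not in (0, 1):
            raise SchemaError(f"{self.participant_id}: event flag must be 0 or 1, got {self.event}")


# ---------------------------------------------------------------------------
# epoch CSV
# ---------------------------------------------------------------------------

def read_epoch_csv(
    path,
    participant_id: Optional[str] = None,
    gap_fill: bool = False,
    skip_header_lines: int = 0,
    off_wrist_policy: str = "missing",
) -> EpochSeries:
    """Read a two-column (timestamp, count) epoch CSV at strict 60-s spacing.

    Parameters
    ----------
    gap_fill
        If True, a gap that is a whole multiple of 60 s is filled with explicit
        missing epochs; otherwise any gap raises :class:`MalformedEpochFile`.
    skip_header_lines
        Device-export preamble lines to skip before the CSV header.
    off_wrist_policy
        ``"missing"`` (default) or ``"exclude"`` turn epochs flagged in an
        optional ``off_wrist`` column into missing epochs; ``"keep"`` ignores
        the flag. The recording itself never distinguishes the two removal
        policies downstream — both mark the epoch missing.
    """
    df = pd.read_csv(path, skiprows=skip_header_lines)
    if df.shape[0] == 0:
        raise EmptySeries(f"{path}: no epochs")
    cols = [c.strip().lower() for c in df.columns]
    df.columns = cols
    if "timestamp" not in cols or "count" not in cols:
        raise MalformedEpochFile(f"{path}: expected columns timestamp,count, got {cols}")

    ts = pd.to_datetime(df["timestamp"], errors="coerce")
    if ts.isna().any():
        raise MalformedEpochFile(f"{path}: unparseable timestamps")

    raw = df["count"]
    counts = pd.to_numeric(raw, errors="coerce").to_numpy(dtype=float)
    # blank cells are missing; anything else must be a non-negative integer
    blank = raw.isna() | (raw.astype(str).str.strip() == "")
    bad = np.isnan(counts) & ~blank.to_numpy()
    if bad.any():
        raise MalformedEpochFile(f"{path}: non-numeric counts")
    present = ~np.isnan(counts)
    if np.any(counts[present] < 0):
        raise MalformedEpochFile(f"{path}: negative counts")
    if np.any(counts[present] != np.round(counts[present])):
        raise MalformedEpochFile(f"{path}: non-integer counts")

    if "off_wrist" in cols and off_wrist_policy in ("missing", "exclude"):
        flag = pd.to_numeric(df["off_wrist"], errors="coerce").fillna(0).to_numpy() != 0
        counts = counts.copy()
        counts[flag] = np.nan

    diffs = ts.diff().dropna().dt.total_seconds().to_numpy()
    if len(diffs) and not np.all(diffs == EPOCH_SECONDS):
        if np.any(diffs <= 0):
            raise MalformedEpochFile(f"{path}: timestamps not strictly increasing")
        if np.any(diffs % EPOCH_SECONDS != 0) or not gap_fill:
            raise MalformedEpochFile(
                f"{path}: irregular epoch spacing (set gap_fill=True to insert missing epochs)"
            )
        full_index = pd.date_range(ts.iloc[0], ts.iloc[-1], freq="60s")
        series = pd.Series(counts, index=ts.values).reindex(full_index)
        counts = series.to_numpy(dtype=float)
        ts = pd.Series(full_index)

    pid = participant_id
    if pid is None:
        pid = df["participant_id"].iloc[0] if "participant_id" in cols else str(path)
    return EpochSeries(participant_id=str(pid), start_time=ts.iloc[0], counts=counts)


def write_epoch_csv(series: EpochSeries, path) -> None:
    counts = pd.array(
        [int(c) if not np.isnan(c) else None for c in series.counts], dtype="Int64"
    )
    pd.DataFrame({"timestamp": series.timestamps, "count": counts}).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# diary CSV
# ---------------------------------------------------------------------------

def read_diary_csv(path) -> list:
    """Read the per-night sleep-diary table; one :class:`DiaryNight` per row."""
    df = pd.read_csv(path, dtype={"participant_id": str})
    missing_cols = set(DIARY_COLUMNS) - set(df.columns)
    if missing_cols:
        raise SchemaError(f"{path}: diary columns missing: {sorted(missing_cols)}")

    def num(v):
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return None
        return float(v)

    nights = []
    for _, row in df.iterrows():
        nights.append(
            DiaryNight(
                participant_id=row["participant_id"],
                night_index=int(row["night_index"]),
                bed_time=parse_clock(row["bed_time"]),
                time_tried_sleep=parse_clock(row["time_tried_sleep"]),
                sol_min=num(row["sol_min"]),
                waso_min=num(row["waso_min"]),
                n_awakenings=num(row["n_awakenings"]),
                final_awakening=parse_clock(row["final_awakening"]),
                get_up_time=parse_clock(row["get_up_time"]),
            )
        )
    seen = set()
    for n in nights:
        key = (n.participant_id, n.night_index)
        if key in seen:
            raise SchemaError(f"duplicate diary night {key}")
        seen.add(key)
    return nights


def write_diary_csv(nights: Sequence[DiaryNight], path) -> None:
    rows = []
    for n in nights:
        rows.append(
            {
                "participant_id": n.participant_id,
                "night_index": n.night_index,
                "bed_time": format_clock(n.bed_time),
                "time_tried_sleep": format_clock(n.time_tried_sleep),
                "sol_min": "" if n.sol_min is None else n.sol_min,
                "waso_min": "" if n.waso_min is None else n.waso_min,
                "n_awakenings": "" if n.n_awakenings is None else n.n_awakenings,
                "final_awakening": format_clock(n.final_awakening),
                "get_up_time": format_clock(n.get_up_time),
            }
        )
    pd.DataFrame(rows, columns=DIARY_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# schedule CSV (event-marker / diary derived in-bed intervals)
# ---------------------------------------------------------------------------

def read_schedule_csv(path) -> dict:
    """Read per-night in-bed intervals; returns {participant_id: BedSchedule}."""
    df = pd.read_csv(path, dtype={"participant_id": str})
    for col in ("participant_id", "in_bed_start", "out_of_bed_end"):
        if col not in df.columns:
            raise SchemaError(f"{path}: schedule column {col!r} missing")
    out = {}
    for pid, grp in df.groupby("participant_id", sort=False):
        ivs = [
            (pd.Timestamp(a), pd.Timestamp(b))
            for a, b in zip(grp["in_bed_start"], grp["out_of_bed_end"])
        ]
        ivs.sort(key=lambda p: p[0])
        out[pid] = BedSchedule(participant_id=pid, intervals=ivs)
    return out


def write_schedule_csv(schedules: dict, path) -> None:
    rows = []
    for pid, sched in schedules.items():
        for a, b in sched.intervals:
            rows.append({"participant_id": pid, "in_bed_start": a, "out_of_bed_end": b})
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# clinical CSV
# ---------------------------------------------------------------------------

def read_clinical_csv(path, schema) -> list:
    """Read the clinical table, typing each predictor column per the schema.

    ``schema`` is a :class:`restwatch.feature_assembly.FeatureSchema`. Unknown
    columns are rejected unless listed in ``schema.ignore``. Values are parsed
    (ordinal levels validated, clock times parsed) but NOT encoded — encoding
    belongs to feature_assembly.
    """
    df = pd.read_csv(path, dtype={"participant_id": str})
    required = {"participant_id", "survival_days", "event"}
    if not required <= set(df.columns):
        raise SchemaError(f"{path}: clinical table must contain {sorted(required)}")
    known = {f.name for f in schema.features}
    for col in df.columns:
        if col in required:
            continue
        if col not in known and col not in schema.ignore:
            raise SchemaError(f"{path}: unknown column {col!r} not in schema")

    records = []
    for _, row in df.iterrows():
        values = {}
        for f in schema.features:
            if f.name not in df.columns:
                continue
            v = row[f.name]
            if pd.isna(v) or (isinstance(v, str) and v.strip() == ""):
                values[f.name] = None
                continue
            schema.validate_value(f, v)
            values[f.name] = v
        ev = row["event"]
        if pd.isna(ev) or float(ev) not in (0.0, 1.0):
            raise SchemaError(f"{path}: event flag must be 0/1, got {ev!r}")
        records.append(
            ClinicalRecord(
                participant_id=row["participant_id"],
                values=values,
                survival_days=float(row["survival_days"]),
                event=int(ev),
            )
        )
    return records
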