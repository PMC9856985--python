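"""Rest-activity rhythm metrics from minute-epoch wrist actigraphy.

The central statistic is the dichotomy index I<O: the percentage of in-bed
epoch activity counts strictly inferior to the median of the out-of-bed
counts. An I<O of 97.5% or below flags a disrupted rest-activity rhythm.
Also provided: the 24-h lag autocorrelation r24 (day-to-day reproducibility
of the activity pattern), mean daily activity (MDA), mean activity during
daytime wakefulness, and the analysis-set qualification rules (per-protocol =
eight consecutive valid 24-h wear periods with diary; full-analysis = at
least three).

All metrics use order statistics or plain moments of the raw counts; missing
epochs (NaN) are excluded pairwise, never zero-filled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import AllMissing, NoInBedEpochs, NoWakeSpan, SeriesTooShort
from .io_formats import EPOCH_SECONDS, BedSchedule, EpochSeries

DISRUPTED_CUTOFF_PCT = 97.5  # I<O at or below this flags a disrupted rhythm
MINUTES_PER_DAY = 1440


@dataclass
class RestActivityMetrics:
    participant_id: str
    i_less_o_pct: float
    r24: float
    mda: float
    wake_activity: float
    n_valid_days: int
    analysis_set: str
    i_less_o_20h_pct: Optional[float] = None

    @property
    def disrupted(self) -> bool:
        return self.i_less_o_pct <= DISRUPTED_CUTOFF_PCT


# ---------------------------------------------------------------------------
# epoch masks
# ---------------------------------------------------------------------------

def in_bed_mask(series: EpochSeries, schedule: BedSchedule) -> np.ndarray:
    """Boolean mask over series epochs: epoch start falls in an in-bed interval."""
    mask = np.zeros(len(series), dtype=bool)
    n = len(series)
    for start, end in schedule.intervals:
        i0 = max(0, int(np.ceil((start - series.start_time).total_seconds() / EPOCH_SECONDS)))
        i1 = min(n, int(np.ceil((end - series.start_time).total_seconds() / EPOCH_SECONDS)))
        if i1 > i0:
            mask[i0:i1] = True
    return mask


def _boundary_exclusion_mask(series: EpochSeries, schedule: BedSchedule, pad_min: int = 60) -> np.ndarray:
    """Epochs within ``pad_min`` minutes either side of each in-bed boundary."""
    mask = np.zeros(len(series), dtype=bool)
    n = len(series)
    pad = pd.Timedelta(minutes=pad_min)
    for start, end in schedule.intervals:
        for t in (start, end):
            i0 = max(0, int(np.ceil((t - pad - series.start_time).total_seconds() / EPOCH_SECONDS)))
            i1 = min(n, int(np.ceil((t + pad - series.start_time).total_seconds() / EPOCH_SECONDS)))
            if i1 > i0:
                mask[i0:i1] = True
    return mask


# ---------------------------------------------------------------------------
# dichotomy index
# ---------------------------------------------------------------------------

def dichotomy_index(
    series: EpochSeries,
    schedule: BedSchedule,
    restriction: str = "none",
    strict: bool = True,
    epoch_mask: Optional[np.ndarray] = None,
) -> float:
    """Dichotomy index I<O as a percentage in [0, 100].

    100 x (# in-bed epochs with count strictly below the pooled out-of-bed
    median) / (# in-bed epochs with a non-missing count).  "Inferior to the
    median" is strict ``<`` by default; ``strict=False`` switches to ``<=``
    for sensitivity analysis.

    ``restriction="20h"`` drops the hour before/after each in-bed boundary
    from both pools. ``epoch_mask`` optionally restricts both pools to a
    subset of epochs (used for per-day, first-72-h and weekday/weekend
    variants).
    """
    if restriction not in ("none", "20h"):
        raise ValueError(f"unknown restriction {restriction!r}")
    counts = series.counts
    inbed = in_bed_mask(series, schedule)
    keep = ~np.isnan(counts)
    if epoch_mask is not None:
        keep = keep & np.asarray(epoch_mask, dtype=bool)
    if restriction == "20h":
        keep = keep & ~_boundary_exclusion_mask(series, schedule, pad_min=60)

    out_pool = counts[keep & ~inbed]
    in_pool = counts[keep & inbed]
    if in_pool.size == 0:
        if not inbed.any():
            raise NoInBedEpochs(f"{series.participant_id}: schedule yields no in-bed epochs")
        raise AllMissing(f"{series.participant_id}: all in-bed epochs missing")
    if out_pool.size == 0:
        raise AllMissing(f"{series.participant_id}: no non-missing out-of-bed epochs")

    med = np.median(out_pool)
    below = in_pool < med if strict else in_pool <= med
    return 100.0 * below.sum() / in_pool.size


def day_window_mask(series: EpochSeries, day_indices: Sequence[int]) -> np.ndarray:
    """Mask selecting whole 24-h wear blocks (1440 epochs from recording start)."""
    mask = np.zeros(len(series), dtype=bool)
    for d in day_indices:
        mask[d * MINUTES_PER_DAY : (d + 1) * MINUTES_PER_DAY] = True
    return mask


def weekday_mask(series: EpochSeries, weekend: bool = False) -> np.ndarray:
    """Mask selecting epochs on Sat/Sun (weekend=True) or Mon-Fri."""
    dow = series.timestamps.dayofweek.to_numpy()
    return (dow >= 5) if weekend else (dow < 5)


def daily_dichotomy(
    series: EpochSeries, schedule: BedSchedule, strict: bool = True
) -> np.ndarray:
    """Per-24-h-block I<O values (NaN where a block lacks either pool)."""
    n_days = len(series) // MINUTES_PER_DAY
    out = np.full(n_days, np.nan)
    for d in range(n_days):
        try:
            out[d] = dichotomy_index(
                series, schedule, strict=strict, epoch_mask=day_window_mask(series, [d])
            )
        except (NoInBedEpochs, AllMissing):
            pass
    return out


# ---------------------------------------------------------------------------
# r24, MDA, wake activity
# ---------------------------------------------------------------------------

def r24_autocorrelation(series: EpochSeries) -> float:
    """Pearson autocorrelation of the count series at a 1440-epoch (24-h) lag.

    Computed over pairwise non-missing (x_t, x_{t+1440}) pairs; at least 1440
    pairs are required, i.e. the series must span >= 48 h of usable data.
    """
    x = series.counts
    if len(x) < 2 * MINUTES_PER_DAY:
        raise SeriesTooShort(
            f"{series.participant_id}: need >= {2 * MINUTES_PER_DAY} epochs for r24, got {len(x)}"
        )
    a = x[:-MINUTES_PER_DAY]
    b = x[MINUTES_PER_DAY:]
    ok = ~np.isnan(a) & ~np.isnan(b)
    if ok.sum() < MINUTES_PER_DAY:
        raise SeriesTooShort(
            f"{series.participant_id}: only {int(ok.sum())} paired epochs at lag 1440"
        )
    a, b = a[ok], b[ok]
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        raise SeriesTooShort(f"{series.participant_id}: constant series, r24 undefined")
    return float(np.corrcoef(a, b)[0, 1])


def mean_daily_activity(series: EpochSeries) -> float:
    """Average wrist movements per minute over the whole recording (MDA)."""
    ok = ~np.isnan(series.counts)
    if not ok.any():
        raise AllMissing(f"{series.participant_id}: all epochs missing")
    return float(series.counts[ok].mean())


def mean_wake_activity(series: EpochSeries, schedule: BedSchedule) -> float:
    """Mean counts/min over epochs strictly between consecutive in-bed intervals."""
    if len(schedule) < 2:
        raise NoWakeSpan(f"{series.participant_id}: need >= 2 in-bed intervals")
    n = len(series)
    mask = np.zeros(n, dtype=bool)
    for (_, end0), (start1, _) in zip(schedule.intervals, schedule.intervals[1:]):
        i0 = max(0, int(np.ceil((end0 - series.start_time).total_seconds() / EPOCH_SECONDS)))
        i1 = min(n, int(np.ceil((start1 - series.start_time).total_seconds() / EPOCH_SECONDS)))
        if i1 > i0:
            mask[i0:i1] = True
    vals = series.counts[mask & ~np.isnan(series.counts)]
    if vals.size == 0:
        raise NoWakeSpan(f"{series.participant_id}: wake spans contain no usable epochs")
    return float(vals.mean())


# ---------------------------------------------------------------------------
# analysis-set qualification
# ---------------------------------------------------------------------------

def valid_days(series: EpochSeries, min_nonmissing_frac: float = 0.9) -> np.ndarray:
    """Validity of each complete 24-h wear block (>= 90% non-missing epochs)."""
    n_days = len(series) // MINUTES_PER_DAY
    out = np.zeros(n_days, dtype=bool)
    for d in range(n_days):
        block = series.counts[d * MINUTES_PER_DAY : (d + 1) * MINUTES_PER_DAY]
        out[d] = (~np.isnan(block)).mean() >= min_nonmissing_frac
    return out


def _longest_true_run(flags: np.ndarray) -> int:
    best = cur = 0
    for f in flags:
        cur = cur + 1 if f else 0
        best = max(best, cur)
    return best


def qualify_analysis_set(
    series: Optional[EpochSeries],
    schedule: Optional[BedSchedule],
    diary_nights: Optional[Sequence],
    min_nonmissing_frac: float = 0.9,
    per_protocol_days: int = 8,
    full_analysis_days: int = 3,
) -> str:
    """Classify a participant as per_protocol / full_analysis / excluded.

    Per protocol: eight consecutive valid 24-h wear periods with the
    corresponding diary. Full analysis: at least three consecutive valid 24-h
    periods with the corresponding diary nights. Otherwise excluded.
    ``diary_nights=None`` waives the diary requirement (actigraphy-only
    qualification, e.g. when no diary table is supplied).
    """
    n_diary = np.inf if diary_nights is None else len(diary_nights)
    run = 0
    if series is not None:
        run = _longest_true_run(valid_days(series, min_nonmissing_frac))
    if run >= per_protocol_days and n_diary >= per_protocol_days:
        return "per_protocol"
    if run >= full_analysis_days and n_diary >= full_analysis_days:
        return "full_analysis"
    return "excluded"


def compute_metrics(
    series: EpochSeries,
    schedule: BedSchedule,
    diary_nights: Optional[Sequence] = None,
    strict: bool = True,
    min_nonmissing_frac: float = 0.9,
) -> Optional[RestActivityMetrics]:
    """All rest-activity metrics for one participant, or None if excluded.

    Metrics are only emitted for participants with at least three consecutive
    valid 24-h wear periods (the full-analysis rule).
    """
    analysis_set = qualify_analysis_set(
        series, schedule, diary_nights, min_nonmissing_frac=min_nonmissing_frac
    )
    n_valid = int(valid_days(series, min_nonmissing_frac).sum())
    if analysis_set == "excluded":
        return None
    return RestActivityMetrics(
        participant_id=series.participant_id,
        i_less_o_pct=dichotomy_index(series, schedule, strict=strict),
        r24=r24_autocorrelation(series),
        mda=mean_daily_activity(series),
        wake_activity=mean_wake_activity(series, schedule),
        n_valid_days=n_valid,
        analysis_set=analysis_set,
        i_less_o_20h_pct=dichotomy_index(series, schedule, restriction="20h", strict=strict),
    )
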