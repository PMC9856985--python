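"""Sleep/wake scoring and per-night sleep parameters.

Two parallel routes produce the same per-night parameter set (BT, GUT, TIB,
SOL, TST, SE, WASO, NA, plus diary-only TWAK):

* actigraphy: counts inside each in-bed interval are scored sleep/wake with
  the published Actiware weighted five-epoch window (weights
  0.04/0.2/1/0.2/0.04 at 1-min epochs, medium sensitivity threshold 40), then
  parameters are read off the label runs;
* diary: the consensus-sleep-diary arithmetic
  TIB = GUT - BT, TWAK = GUT - final awakening,
  TST = TIB - (SOL + WASO + TWAK), SE = 100 * TST / TIB.

Clock times are held as minutes since midnight and ordered on a 12:00->36:00
axis (times before noon shifted +24 h) so bedtimes spanning midnight compare
correctly. Participant-level aggregates average clock times circularly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import (
    InconsistentTimes,
    IntervalOutsideSeries,
    NoSleepDetected,
    TooFewNights,
)
from .io_formats import (
    EPOCH_SECONDS,
    DiaryNight,
    EpochSeries,
    to_axis_minutes,
)

#: Actiware-style weights for epochs -2..+2 around the scored epoch
SCORE_WEIGHTS = np.array([0.04, 0.2, 1.0, 0.2, 0.04])
DEFAULT_THRESHOLD = 40.0  # medium sensitivity; 20 = high, 80 = low
ONSET_RUN_MIN = 10  # consecutive sleep minutes defining sleep onset


@dataclass
class SleepNight:
    participant_id: str
    night_index: int
    source: str  # "actigraphy" | "diary"
    bt: Optional[float]  # minutes since midnight
    gut: Optional[float]
    tib_min: Optional[float]
    sol_min: Optional[float]
    tst_min: Optional[float]
    se_pct: Optional[float]
    waso_min: Optional[float]
    na: Optional[float]
    twak_min: Optional[float] = None  # diary only
    flagged: bool = False  # inconsistent diary arithmetic (TST clamped to missing)

    def __post_init__(self):
        if self.se_pct is not None and not (0.0 <= self.se_pct <= 100.0 + 1e-9):
            raise InconsistentTimes(f"SE {self.se_pct} outside [0, 100]")
        if self.tst_min is not None and self.tib_min is not None:
            if self.tst_min > self.tib_min + 1e-9:
                raise InconsistentTimes("TST exceeds TIB")


# ---------------------------------------------------------------------------
# actigraphy scoring
# ---------------------------------------------------------------------------

def score_epochs(series: EpochSeries, interval, threshold: float = DEFAULT_THRESHOLD) -> np.ndarray:
    """Label each epoch of an in-bed interval sleep (True) or wake (False).

    The weighted score W = 0.04*(c-2 + c+2) + 0.2*(c-1 + c+1) + c0 uses
    neighbouring epochs from the full recording where available; missing
    neighbours (and epochs beyond the recording) contribute zero weight. An
    epoch sleeps iff W <= threshold.
    """
    start, end = pd.Timestamp(interval[0]), pd.Timestamp(interval[1])
    i0 = int(round((start - series.start_time).total_seconds() / EPOCH_SECONDS))
    i1 = int(round((end - series.start_time).total_seconds() / EPOCH_SECONDS))
    if i0 < 0 or i1 > len(series) or i1 <= i0:
        raise IntervalOutsideSeries(
            f"{series.participant_id}: interval [{start}, {end}] not covered by the recording"
        )
    counts = np.nan_to_num(series.counts, nan=0.0)
    w = np.convolve(counts, SCORE_WEIGHTS, mode="same")
    return w[i0:i1] <= threshold


def _runs(labels: np.ndarray):
    """Run-length encode: yields (value, start, length)."""
    i = 0
    n = len(labels)
    while i < n:
        j = i
        while j < n and labels[j] == labels[i]:
            j += 1
        yield bool(labels[i]), i, j - i
        i = j


def actigraphy_night_params(
    labels: np.ndarray,
    interval,
    participant_id: str = "",
    night_index: int = 0,
    onset_run: int = ONSET_RUN_MIN,
) -> SleepNight:
    """Per-night parameters from sleep/wake labels over one in-bed interval.

    Sleep onset = start of the first run of >= ``onset_run`` consecutive
    sleep-scored minutes; final awakening = end of the last such run. TST
    counts sleep minutes between onset and final awakening, WASO the wake
    minutes in between, NA the number of contiguous wake blocks in between.
    SE = 100 * TST / TIB with TIB the interval length.
    """
    labels = np.asarray(labels, dtype=bool)
    start, end = pd.Timestamp(interval[0]), pd.Timestamp(interval[1])
    tib = len(labels)
    if tib == 0:
        raise IntervalOutsideSeries("empty in-bed interval")

    sleep_runs = [(s, ln) for val, s, ln in _runs(labels) if val and ln >= onset_run]
    if not sleep_runs:
        raise NoSleepDetected(f"{participant_id}: no run of {onset_run} sleep minutes")
    onset = sleep_runs[0][0]
    final_awakening = sleep_runs[-1][0] + sleep_runs[-1][1]  # end of last qualifying run

    period = labels[onset:final_awakening]
    tst = int(period.sum())
    waso = int(len(period) - tst)
    na = sum(1 for val, _, _ in _runs(period) if not val)

    bt_min = start.hour * 60 + start.minute
    gut_min = end.hour * 60 + end.minute
    return SleepNight(
        participant_id=participant_id,
        night_index=night_index,
        source="actigraphy",
        bt=float(bt_min),
        gut=float(gut_min),
        tib_min=float(tib),
        sol_min=float(onset),
        tst_min=float(tst),
        se_pct=100.0 * tst / tib,
        waso_min=float(waso),
        na=float(na),
    )


# ---------------------------------------------------------------------------
# diary arithmetic
# ---------------------------------------------------------------------------

def _axis_duration(later: float, earlier: float) -> float:
    """Minutes from ``earlier`` to ``later`` clock times, cross-midnight aware."""
    a, b = to_axis_minutes(earlier), to_axis_minutes(later)
    if b < a:
        b += 24 * 60
    return b - a


def diary_night_params(d: DiaryNight) -> SleepNight:
    """Per-night parameters from one diary row using the published arithmetic.

    TIB = GUT - BT; TWAK = GUT - final awakening; TST = TIB - (SOL + WASO +
    TWAK); SE = 100 * TST / TIB. A night whose reported durations exceed TIB
    gets TST/SE clamped to missing and is flagged rather than erroring.
    """
    if d.bed_time is None or d.get_up_time is None or d.final_awakening is None:
        raise InconsistentTimes(
            f"{d.participant_id} night {d.night_index}: BT/GUT/final awakening required"
        )
    tib = _axis_duration(d.get_up_time, d.bed_time)
    if tib <= 0 or tib >= 24 * 60:
        raise InconsistentTimes(f"{d.participant_id} night {d.night_index}: TIB {tib} min")
    twak = _axis_duration(d.get_up_time, d.final_awakening)
    if twak > tib:  # final awakening before bed time
        raise InconsistentTimes(
            f"{d.participant_id} night {d.night_index}: final awakening outside the night"
        )

    sol = d.sol_min
    waso = d.waso_min
    tst = se = None
    flagged = False
    if sol is not None and waso is not None:
        tst = tib - (sol + waso + twak)
        if tst < 0:
            tst = None
            flagged = True
        else:
            se = 100.0 * tst / tib
    return SleepNight(
        participant_id=d.participant_id,
        night_index=d.night_index,
        source="diary",
        bt=d.bed_time,
        gut=d.get_up_time,
        tib_min=tib,
        sol_min=sol,
        tst_min=tst,
        se_pct=se,
        waso_min=waso,
        na=d.n_awakenings,
        twak_min=twak,
        flagged=flagged,
    )


# ---------------------------------------------------------------------------
# participant-level aggregation
# ---------------------------------------------------------------------------

def circular_mean_clock(minutes: Sequence[float]) -> float:
    """Circular mean of clock times in minutes since midnight, in [0, 1440)."""
    vals = np.asarray([m for m in minutes if m is not None], dtype=float)
    theta = vals / 1440.0 * 2 * np.pi
    mean_angle = np.arctan2(np.sin(theta).mean(), np.cos(theta).mean())
    out = float((mean_angle / (2 * np.pi) * 1440.0) % 1440.0)
    return 0.0 if out >= 1440.0 - 1e-9 else out


_DURATION_FIELDS = ("tib_min", "sol_min", "tst_min", "se_pct", "waso_min", "na", "twak_min")
_CLOCK_FIELDS = ("bt", "gut")


def aggregate_participant(nights: Sequence[SleepNight], min_nights: int = 3) -> dict:
    """Participant-level means over available nights (one source at a time).

    Numeric fields are averaged arithmetically over non-missing nights;
    BT/GUT are averaged circularly so e.g. 23:30 and 00:30 average to 00:00.
    """
    if len(nights) < min_nights:
        raise TooFewNights(f"need >= {min_nights} nights, got {len(nights)}")
    sources = {n.source for n in nights}
    if len(sources) != 1:
        raise ValueError("aggregate one source at a time")
    out = {"participant_id": nights[0].participant_id, "source": nights[0].source,
           "n_nights": len(nights)}
    for f in _DURATION_FIELDS:
        vals = [getattr(n, f) for n in nights if getattr(n, f) is not None]
        out[f] = float(np.mean(vals)) if vals else None
    for f in _CLOCK_FIELDS:
        vals = [getattr(n, f) for n in nights if getattr(n, f) is not None]
        out[f] = circular_mean_clock(vals) if vals else None
    return out
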