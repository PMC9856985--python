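"""Synthetic study-cohort generator with known ground truth.

Emulates the structure of the study inputs so the whole pipeline is testable
without any participant data: minute-epoch wrist actigraphy over eight 24-h
wear periods, a consensus sleep diary correlated with the actigraphy, a
66-predictor clinical table, and exponential survival with administrative
censoring and a known sparse effect vector.

The activity model is a two-state (sleep/wake) semi-Markov process inside
scheduled nights. A per-participant fragmentation parameter rho controls the
per-minute rate of nocturnal wake-bout initiation; counts are drawn
negative-binomially (wrist counts are overdispersed) with state-dependent
means, the wake mean modulated by a 24-h sinusoid. A latent frailty drives
rho upward and the daytime mean downward, so the dichotomy index I<O
decreases with frailty by construction, and the same frailty enters the
survival hazard — giving the derived actigraphy features genuine prognostic
signal and realistic collinearity with the clinical covariates.

Recordings start at 12:00 so each 1440-epoch wear block contains one whole
night. Ground truth (frailty, rho, true sleep state, true event time) is
retained beside the outputs and is never read by the analysis path.
"""

from __future__ import annotations

import pathlib
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .feature_assembly import (
    ClinicalRecord,
    FeatureSchema,
    default_schema,
    encode_value,
)
from .io_formats import (
    BedSchedule,
    DiaryNight,
    EpochSeries,
    format_clock,
    write_diary_csv,
    write_epoch_csv,
    write_schedule_csv,
)

MINUTES_PER_DAY = 1440

#: sparse true effects on standardised encoded predictors (positive = harmful)
DEFAULT_TRUE_BETA = {
    "pips_clinician_survival_estimate": -0.40,
    "pips_global_health": -0.30,
    "haemoglobin": -0.30,
    "ecog_clinician_day0": 0.35,
    "psqi_subjective_sleep_quality": 0.25,
    "opioid_use": 0.30,
    "neutrophils": 0.30,
    "urea": 0.30,
    "creatinine": 0.25,
    "crp": 0.40,
}


@dataclass
class CohortSpec:
    """All generator conditions; the defaults mirror the study's data structure."""

    n_participants: int = 50
    days_per_participant: int = 8
    epoch_seconds: int = 60
    rho_range: tuple = (0.005, 0.14)  # nocturnal wake-bout initiation prob/min
    amplitude_range: tuple = (0.3, 0.7)  # 24-h modulation of the wake count mean
    day_mean_base: float = 250.0  # counts/min, daytime wake, healthiest
    day_mean_frailty_drop: float = 0.45  # fractional reduction at high frailty
    sleep_mean: float = 3.0  # counts/min while asleep
    nb_dispersion: float = 1.5  # negative-binomial size parameter
    true_beta: dict = field(default_factory=lambda: dict(DEFAULT_TRUE_BETA))
    frailty_effect: float = 0.4  # hazard log-effect of the latent frailty
    baseline_hazard: float = np.log(2) / 110.0  # per day; gives ~68% events by day 365
    admin_censor_day: float = 365.0
    diary_clock_sd_min: float = 10.0
    diary_duration_cv: float = 0.15
    seed: int = 0
    start: pd.Timestamp = pd.Timestamp("2019-03-04 12:00")  # a Monday noon

    def __post_init__(self):
        if self.n_participants < 2:
            raise ValueError("need n >= 2")
        if self.days_per_participant < 3:
            raise ValueError("need >= 3 days")
        if self.epoch_seconds != 60:
            raise ValueError("epoch length is fixed at 60 s")


def strong_signal_spec(**overrides) -> CohortSpec:
    """Spec with doubled effect sizes, for power / recovery experiments."""
    beta = {k: 2.0 * v for k, v in DEFAULT_TRUE_BETA.items()}
    kw = dict(true_beta=beta, frailty_effect=0.6)
    kw.update(overrides)
    return CohortSpec(**kw)


@dataclass
class GroundTruth:
    participant_id: str
    frailty: float
    rho: float
    day_mean: float
    amplitude: float
    sleep_state: np.ndarray  # True = asleep, per epoch
    nights: list  # per-night dicts with true BT/GUT/SOL/WASO/NA/final awakening


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _nb_draw(rng, mean, dispersion):
    """Negative-binomial counts with the given means and size ``dispersion``."""
    mean = np.maximum(np.asarray(mean, dtype=float), 1e-9)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p).astype(float)


# ---------------------------------------------------------------------------
# activity
# ---------------------------------------------------------------------------

def simulate_activity(
    spec: CohortSpec,
    participant_id: str,
    rng: np.random.Generator,
    frailty: Optional[float] = None,
    rho: Optional[float] = None,
):
    """One participant's epoch series, bed schedule and ground truth.

    ``frailty`` and ``rho`` can be pinned for controlled experiments;
    otherwise frailty ~ N(0,1) and rho is its sigmoid mapped into
    ``spec.rho_range``.
    """
    if frailty is None:
        frailty = float(rng.normal())
    sig = _sigmoid(frailty)
    if rho is None:
        lo, hi = spec.rho_range
        rho = lo + (hi - lo) * sig
    day_mean = spec.day_mean_base * (1.0 - spec.day_mean_frailty_drop * sig)
    amp = float(rng.uniform(*spec.amplitude_range))

    n_epochs = spec.days_per_participant * MINUTES_PER_DAY
    start = spec.start
    asleep = np.zeros(n_epochs, dtype=bool)
    in_bed = np.zeros(n_epochs, dtype=bool)

    intervals = []
    nights = []
    for d in range(spec.days_per_participant):
        bed_min = d * MINUTES_PER_DAY + 11 * 60 + int(round(rng.normal(0, 20)))  # ~23:00
        gut_min = (d + 1) * MINUTES_PER_DAY + 7 * 60 + int(round(rng.normal(0, 20)))  # ~07:00
        bed_min = int(np.clip(bed_min, d * MINUTES_PER_DAY + 9 * 60, d * MINUTES_PER_DAY + 13 * 60 - 1))
        gut_min = int(np.clip(gut_min, (d + 1) * MINUTES_PER_DAY + 5 * 60, min(n_epochs, (d + 1) * MINUTES_PER_DAY + 9 * 60)))
        tib = gut_min - bed_min
        in_bed[bed_min:gut_min] = True

        # latency and terminal wakefulness scale with fragmentation: rho = 0
        # reproduces a night with no in-bed wakefulness at all
        sol = min(int(round(rng.exponential(40.0 * rho))) if rho > 0 else 0, tib // 3)
        twak = min(int(round(rng.exponential(20.0 * rho))) if rho > 0 else 0, tib // 4)
        onset = bed_min + sol
        final_awak = gut_min - twak
        asleep[onset:final_awak] = True

        # wake bouts inside the sleep period: initiation ~ Bernoulli(rho)/min,
        # bout length 1 + Geometric(0.3) minutes
        waso = 0
        na = 0
        t = onset
        while t < final_awak:
            if asleep[t] and rng.random() < rho:
                bout = 1 + int(rng.geometric(0.3))
                end = min(t + bout, final_awak)
                asleep[t:end] = False
                waso += end - t
                na += 1
                t = end
            else:
                t += 1

        intervals.append(
            (start + pd.Timedelta(minutes=bed_min), start + pd.Timedelta(minutes=gut_min))
        )
        nights.append(
            {
                "night_index": d,
                "bed_min": bed_min,
                "gut_min": gut_min,
                "sol": sol,
                "waso": waso,
                "na": na,
                "twak": twak,
                "final_awak_min": final_awak,
            }
        )

    hours = (np.arange(n_epochs) + start.hour * 60 + start.minute) / 60.0 % 24.0
    wake_mean = day_mean * np.maximum(0.05, 1.0 + amp * np.cos(2 * np.pi * (hours - 15.0) / 24.0))
    means = np.where(asleep, spec.sleep_mean, wake_mean)
    counts = _nb_draw(rng, means, spec.nb_dispersion)

    series = EpochSeries(participant_id=participant_id, start_time=start, counts=counts)
    schedule = BedSchedule(participant_id=participant_id, intervals=intervals)
    truth = GroundTruth(
        participant_id=participant_id,
        frailty=frailty,
        rho=float(rho),
        day_mean=float(day_mean),
        amplitude=amp,
        sleep_state=asleep,
        nights=nights,
    )
    return series, schedule, truth


# ---------------------------------------------------------------------------
# diary
# ---------------------------------------------------------------------------

def simulate_diary(
    series: EpochSeries,
    schedule: BedSchedule,
    truth: GroundTruth,
    rng: np.random.Generator,
    clock_sd_min: float = 10.0,
    duration_cv: float = 0.15,
) -> list:
    """Diary nights = truth + zero-mean reporting noise, clamped to validity.

    Clock times get ~N(0, clock_sd_min) minute errors, durations a
    multiplicative (1 + cv*Z) error. With both noise scales at zero the diary
    equals the truth exactly. WASO is clamped so SOL + WASO + TWAK never
    exceeds TIB, which keeps the diary arithmetic identity satisfiable.
    """
    out = []
    start = series.start_time
    for night in truth.nights:
        bt_eps = rng.normal(0, clock_sd_min) if clock_sd_min > 0 else 0.0
        gut_eps = rng.normal(0, clock_sd_min) if clock_sd_min > 0 else 0.0
        bed_min = night["bed_min"] + int(round(bt_eps))
        gut_min = night["gut_min"] + int(round(gut_eps))
        if gut_min <= bed_min + 60:
            gut_min = bed_min + 60
        tib = gut_min - bed_min

        def noisy(v):
            if duration_cv <= 0:
                return float(v)
            return max(0.0, float(v) * (1.0 + duration_cv * rng.normal()))

        sol = round(noisy(night["sol"]))
        twak = round(min(noisy(night["twak"]), tib / 4))
        waso = round(min(noisy(night["waso"]), max(0.0, tib - sol - twak)))
        na = max(0, int(round(night["na"] + (rng.normal(0, 1) if duration_cv > 0 else 0))))
        final_awak_min = gut_min - twak

        def clock(total_min):
            t = start + pd.Timedelta(minutes=int(total_min))
            return float(t.hour * 60 + t.minute)

        out.append(
            DiaryNight(
                participant_id=series.participant_id,
                night_index=night["night_index"],
                bed_time=clock(bed_min),
                time_tried_sleep=clock(bed_min + min(10, tib // 10)),
                sol_min=float(sol),
                waso_min=float(waso),
                n_awakenings=float(na),
                final_awakening=clock(final_awak_min),
                get_up_time=clock(gut_min),
            )
        )
    return out


# ---------------------------------------------------------------------------
# clinical covariates and survival
# ---------------------------------------------------------------------------

def simulate_clinical_values(spec: CohortSpec, frailty: float, rng: np.random.Generator) -> dict:
    """Raw clinical + PSQI values for one participant, frailty-linked.

    Several covariates load on the latent frailty so the encoded table shows
    the collinearity a real palliative-care dataset would (performance
    status, inflammation markers, symptom burden all track the same latent
    decline).
    """
    z = frailty

    def ordc(center, slope, sd, lo, hi):
        return int(np.clip(round(center + slope * z + rng.normal(0, sd)), lo, hi))

    psqi_levels = ["not during the past month", "less than once a week",
                   "once or twice a week", "three or more times a week"]
    pips_levels = ["days", "weeks", "months", "year+"]
    vals = {
        "age": float(np.clip(rng.normal(65, 10), 40, 85)),
        "sex": "male" if rng.random() < 0.55 else "female",
        "months_since_diagnosis": float(rng.exponential(18)),
        "bmi": float(np.clip(rng.normal(24, 4), 15, 40)),
        "ecog_clinician_day0": ordc(1.7, 0.8, 0.5, 0, 4),
        "ecog_patient_day0": ordc(1.7, 0.7, 0.6, 0, 4),
        "ecog_clinician_day8": ordc(1.8, 0.8, 0.5, 0, 4),
        "ecog_patient_day8": ordc(1.8, 0.7, 0.6, 0, 4),
        "pips_clinician_survival_estimate": pips_levels[ordc(2.0, -0.7, 0.5, 0, 3)],
        "pips_global_health": ordc(4.0, -1.0, 0.9, 1, 7),
        "pulse": float(np.clip(rng.normal(85 + 4 * z, 12), 50, 140)),
        "mgps": ordc(1.0, 0.6, 0.5, 0, 2),
        "amts": ordc(9.3, -0.3, 0.7, 4, 10),
        "opioid_use": "yes" if rng.random() < _sigmoid(0.6 * z) else "no",
        "haemoglobin": float(np.clip(rng.normal(11.5 - 0.8 * z, 1.4), 6, 17)),
        "wbc": float(np.clip(rng.normal(9 + 1.0 * z, 2.5), 2, 30)),
        "neutrophils": float(np.clip(rng.normal(6.5 + 1.2 * z, 1.8), 0.5, 25)),
        "lymphocytes": float(np.clip(rng.normal(1.4 - 0.2 * z, 0.5), 0.2, 5)),
        "platelets": float(np.clip(rng.normal(300, 80), 50, 800)),
        "sodium": float(np.clip(rng.normal(137 - 0.5 * z, 3), 120, 150)),
        "potassium": float(np.clip(rng.normal(4.2, 0.4), 2.8, 6.5)),
        "urea": float(np.clip(rng.normal(7.5 + 1.8 * z, 2.2), 2, 30)),
        "creatinine": float(np.clip(rng.normal(85 + 18 * z, 20), 40, 300)),
        "albumin": float(np.clip(rng.normal(34 - 2.5 * z, 4), 15, 50)),
        "alt": float(np.clip(rng.normal(30, 12), 5, 200)),
        "alp": float(np.clip(rng.normal(160 + 20 * z, 60), 40, 800)),
        "crp": float(np.clip(rng.normal(45 + 28 * z, 22), 1, 250)),
        "msas_total": float(np.clip(rng.normal(1.2 + 0.3 * z, 0.4), 0, 4)),
        "msas_global_distress": float(np.clip(rng.normal(1.4 + 0.3 * z, 0.5), 0, 4)),
        "msas_physical": float(np.clip(rng.normal(1.3 + 0.3 * z, 0.4), 0, 4)),
        "msas_psych": float(np.clip(rng.normal(1.1 + 0.2 * z, 0.5), 0, 4)),
        "psqi_subjective_sleep_quality": ordc(1.3, 0.5, 0.7, 0, 3),
        "psqi_sleep_latency": ordc(1.4, 0.4, 0.8, 0, 3),
        "psqi_sleep_duration": ordc(1.2, 0.4, 0.8, 0, 3),
        "psqi_habitual_efficiency": ordc(1.3, 0.5, 0.8, 0, 3),
        "psqi_sleep_disturbance": ordc(1.5, 0.5, 0.7, 0, 3),
        "psqi_sleep_medication": ordc(0.8, 0.3, 0.9, 0, 3),
        "psqi_daytime_dysfunction": ordc(1.2, 0.5, 0.8, 0, 3),
        "psqi_usual_bed_time": format_clock((22.8 + rng.normal(0, 0.8)) % 24 * 60),
        "psqi_usual_getup_time": format_clock((7.2 + rng.normal(0, 0.8)) % 24 * 60),
        "psqi_disturb_wake_night": psqi_levels[ordc(1.6, 0.6, 0.8, 0, 3)],
        "psqi_disturb_pain": psqi_levels[ordc(1.4, 0.6, 0.8, 0, 3)],
        "psqi_disturb_cannot_breathe": psqi_levels[ordc(0.9, 0.5, 0.8, 0, 3)],
    }
    return vals


def simulate_survival(
    X: np.ndarray,
    beta: np.ndarray,
    rng: np.random.Generator,
    baseline_hazard: float = np.log(2) / 250.0,
    admin_censor_day: Optional[float] = 365.0,
):
    """Exponential event times with rate lambda0 * exp(X beta), admin censoring.

    Returns (time, event, true_time). With ``admin_censor_day=None`` no
    censoring is applied.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    lp = X @ np.asarray(beta, dtype=float)
    rate = baseline_hazard * np.exp(lp)
    true_t = rng.exponential(1.0 / rate)
    if admin_censor_day is None:
        return true_t, np.ones(len(true_t), dtype=int), true_t
    event = (true_t <= admin_censor_day).astype(int)
    time = np.minimum(true_t, admin_censor_day)
    return time, event, true_t


# ---------------------------------------------------------------------------
# whole-cohort bundle
# ---------------------------------------------------------------------------

@dataclass
class CohortBundle:
    spec: CohortSpec
    schema: FeatureSchema
    series: dict  # pid -> EpochSeries
    schedules: dict  # pid -> BedSchedule
    diaries: list  # DiaryNight
    clinical: list  # ClinicalRecord
    truth: pd.DataFrame  # per-participant latent state and true event time

    @property
    def participant_ids(self) -> list:
        return list(self.series.keys())


def generate_cohort(spec: CohortSpec, out_dir=None) -> CohortBundle:
    """Generate the full input bundle; optionally write it in the CSV dialects.

    The survival linear predictor is ``z(clinical)' beta_true +
    frailty_effect * frailty`` where z() standardises the encoded clinical
    covariates across the cohort, so coefficients are on the standardised
    scale the models estimate.
    """
    schema = default_schema()
    root = np.random.SeedSequence(spec.seed)
    child_seeds = root.spawn(spec.n_participants + 1)

    series, schedules, truths = {}, {}, []
    diaries = []
    clin_vals = []
    for i in range(spec.n_participants):
        pid = f"P{i + 1:03d}"
        rng = np.random.default_rng(child_seeds[i])
        s, sch, tr = simulate_activity(spec, pid, rng)
        series[pid] = s
        schedules[pid] = sch
        truths.append(tr)
        diaries.extend(
            simulate_diary(
                s, sch, tr, rng,
                clock_sd_min=spec.diary_clock_sd_min,
                duration_cv=spec.diary_duration_cv,
            )
        )
        clin_vals.append(simulate_clinical_values(spec, tr.frailty, rng))

    ids = list(series.keys())
    # encode the beta-carrying clinical columns, standardise cohort-wide
    beta_items = sorted(spec.true_beta.items())
    Z = np.zeros((len(ids), len(beta_items)))
    for j, (name, _) in enumerate(beta_items):
        f = schema[name]
        col = np.array([encode_value(f, v[name]) for v in clin_vals])
        sd = col.std()
        Z[:, j] = (col - col.mean()) / (sd if sd > 0 else 1.0)
    beta_vec = np.array([b for _, b in beta_items])
    frail = np.array([t.frailty for t in truths])
    lp = Z @ beta_vec + spec.frailty_effect * frail

    surv_rng = np.random.default_rng(child_seeds[-1])
    time, event, true_t = simulate_survival(
        np.eye(len(ids)), lp, surv_rng,
        baseline_hazard=spec.baseline_hazard,
        admin_censor_day=spec.admin_censor_day,
    )

    clinical = [
        ClinicalRecord(
            participant_id=pid,
            values=dict(vals),
            survival_days=float(time[i]),
            event=int(event[i]),
        )
        for i, (pid, vals) in enumerate(zip(ids, clin_vals))
    ]
    truth_df = pd.DataFrame(
        {
            "participant_id": ids,
            "frailty": frail,
            "rho": [t.rho for t in truths],
            "day_mean": [t.day_mean for t in truths],
            "linear_predictor": lp,
            "true_event_day": true_t,
            "survival_days": time,
            "event": event,
        }
    ).set_index("participant_id")

    bundle = CohortBundle(
        spec=spec, schema=schema, series=series, schedules=schedules,
        diaries=diaries, clinical=clinical, truth=truth_df,
    )
    if out_dir is not None:
        write_cohort(bundle, out_dir)
    return bundle


def write_cohort(bundle: CohortBundle, out_dir) -> None:
    """Write the bundle in the exact input dialects the readers expect."""
    out = pathlib.Path(out_dir)
    (out / "epochs").mkdir(parents=True, exist_ok=True)
    for pid, s in bundle.series.items():
        write_epoch_csv(s, out / "epochs" / f"{pid}.csv")
    write_diary_csv(bundle.diaries, out / "diary.csv")
    write_schedule_csv(bundle.schedules, out / "schedule.csv")

    rows = []
    for rec in bundle.clinical:
        row = {"participant_id": rec.participant_id}
        row.update(rec.values)
        row["survival_days"] = rec.survival_days
        row["event"] = rec.event
        rows.append(row)
    pd.DataFrame(rows).to_csv(out / "clinical.csv", index=False)
    # ground truth sidecar: never read by the analysis path
    bundle.truth.to_csv(out / "ground_truth.csv")
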