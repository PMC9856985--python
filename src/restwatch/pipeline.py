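"""End-to-end orchestration: simulate -> metrics -> sleep -> assemble -> univariate -> fit.

Each stage is a pure function of (inputs, config, seed) and writes tidy CSV /
JSON outputs under the run directory, so later stages can be re-run from disk
(``from_stage``). One global seed expands deterministically into per-stage
seeds.
"""

from __future__ import annotations

import json
import logging
import pathlib
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import rest_activity as ra
from . import sleep_metrics as sm
from . import synthetic
from . import univariate as uv
from .errors import (
    InconsistentTimes,
    NoSleepDetected,
    RestwatchError,
    TooFewNights,
    DegenerateSplit,
)
from .feature_assembly import FeatureSchema, FeatureTable, assemble, default_schema
from .io_formats import (
    read_clinical_csv,
    read_diary_csv,
    read_epoch_csv,
    read_schedule_csv,
)
from .survival_models import (
    STUDY_ALPHAS,
    hazard_survival_correlation,
    km_median_split_eval,
    out_of_fold_hazards,
)

log = logging.getLogger("restwatch")

STAGES = ["simulate", "metrics", "sleep", "assemble", "univariate", "fit"]


@dataclass
class RunConfig:
    out_dir: pathlib.Path
    spec: Optional[synthetic.CohortSpec] = None  # simulate, or ...
    input_dir: Optional[pathlib.Path] = None  # ... read pre-existing inputs
    schema: Optional[FeatureSchema] = None
    alphas: dict = field(default_factory=lambda: dict(STUDY_ALPHAS))
    folds: int = 10
    inner_folds: int = 5
    seed: int = 0
    scoring_threshold: float = sm.DEFAULT_THRESHOLD

    def __post_init__(self):
        self.out_dir = pathlib.Path(self.out_dir)
        if self.schema is None:
            self.schema = default_schema()
        for name, a in self.alphas.items():
            if not (0.0 < a <= 1.0):
                raise ValueError(f"alpha {name}={a} outside (0, 1]")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    idx = STAGES.index(stage)
    return int(np.random.SeedSequence([seed, idx]).generate_state(1)[0] % (2**31))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


# ---------------------------------------------------------------------------
# per-participant derivations
# ---------------------------------------------------------------------------

def derive_participant(series, schedule, diary_nights, scoring_threshold=sm.DEFAULT_THRESHOLD):
    """Rest-activity metrics plus aggregated sleep parameters for one participant.

    Returns (metrics_row, feature_values): the first feeds the univariate
    battery, the second the ML table (feature-schema names).
    """
    pid = series.participant_id
    metrics = ra.compute_metrics(series, schedule, diary_nights)
    row = {"participant_id": pid}
    feats = {}
    if metrics is not None:
        row.update(
            i_less_o=metrics.i_less_o_pct,
            i_less_o_20h=metrics.i_less_o_20h_pct,
            r24=metrics.r24,
            mda=metrics.mda,
            wake_activity=metrics.wake_activity,
            n_valid_days=metrics.n_valid_days,
            analysis_set=metrics.analysis_set,
            disrupted=metrics.disrupted,
        )
        feats.update(
            i_less_o=metrics.i_less_o_pct, r24=metrics.r24,
            mda=metrics.mda, wake_activity=metrics.wake_activity,
        )
    else:
        row.update(analysis_set="excluded")

    # actigraphy sleep nights
    act_nights = []
    for idx, interval in enumerate(schedule.intervals):
        try:
            labels = sm.score_epochs(series, interval, threshold=scoring_threshold)
            act_nights.append(
                sm.actigraphy_night_params(labels, interval, participant_id=pid, night_index=idx)
            )
        except (NoSleepDetected, RestwatchError):
            continue
    diary_param_nights = []
    for d in diary_nights:
        try:
            diary_param_nights.append(sm.diary_night_params(d))
        except InconsistentTimes:
            continue

    key_map = {"bt": "bt", "gut": "gut", "tib": "tib_min", "sol": "sol_min",
               "tst": "tst_min", "se": "se_pct", "waso": "waso_min", "na": "na"}
    for prefix, nights in (("act", act_nights), ("diary", diary_param_nights)):
        try:
            agg = sm.aggregate_participant(nights)
        except TooFewNights:
            continue
        for feat_key, agg_key in key_map.items():
            if agg.get(agg_key) is not None:
                feats[f"{prefix}_{feat_key}"] = agg[agg_key]
        if prefix == "diary" and agg.get("twak_min") is not None:
            feats["diary_twak"] = agg["twak_min"]
    tried = [d.time_tried_sleep for d in diary_nights if d.time_tried_sleep is not None]
    awak = [d.final_awakening for d in diary_nights if d.final_awakening is not None]
    if len(tried) >= 3:
        feats["diary_time_tried_sleep"] = sm.circular_mean_clock(tried)
    if len(awak) >= 3:
        feats["diary_final_awakening"] = sm.circular_mean_clock(awak)

    return row, feats, act_nights, diary_param_nights


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _load_inputs(cfg: RunConfig):
    if cfg.spec is not None:
        sim_dir = cfg.out_dir / "inputs"
        log.info("stage=simulate seed=%d writing %s", cfg.seed, sim_dir)
        spec = cfg.spec
        bundle = synthetic.generate_cohort(spec, out_dir=sim_dir)
        return bundle.series, bundle.schedules, bundle.diaries, bundle.clinical
    indir = pathlib.Path(cfg.input_dir)
    for required in ("diary.csv", "schedule.csv", "clinical.csv"):
        if not (indir / required).exists():
            raise FileNotFoundError(f"input file missing: {indir / required}")
    schedules = read_schedule_csv(indir / "schedule.csv")
    diaries = read_diary_csv(indir / "diary.csv")
    clinical = read_clinical_csv(indir / "clinical.csv", cfg.schema)
    series = {}
    for rec in clinical:
        f = indir / "epochs" / f"{rec.participant_id}.csv"
        if f.exists():
            series[rec.participant_id] = read_epoch_csv(f, rec.participant_id, gap_fill=True)
    return series, schedules, diaries, clinical


def derive_cohort(series, schedules, diaries, clinical, schema,
                  scoring_threshold=sm.DEFAULT_THRESHOLD):
    """metrics + sleep + assemble, in memory.

    Returns (metrics_df, night_rows, table).
    """
    by_pid_diary = {}
    for d in diaries:
        by_pid_diary.setdefault(d.participant_id, []).append(d)
    metric_rows, feat_rows, night_rows = [], {}, []
    for pid, s in series.items():
        sched = schedules.get(pid)
        if sched is None or len(sched) == 0:
            continue
        row, feats, act_nights, diary_nights = derive_participant(
            s, sched, by_pid_diary.get(pid, []), scoring_threshold=scoring_threshold
        )
        metric_rows.append(row)
        feat_rows[pid] = feats
        for n in act_nights + diary_nights:
            night_rows.append(vars(n).copy())
    metrics_df = pd.DataFrame(metric_rows).set_index("participant_id")
    derived = pd.DataFrame.from_dict(feat_rows, orient="index")
    table = assemble(clinical, derived, schema)
    return metrics_df, night_rows, table


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages; returns (and writes) the run report."""
    out = cfg.out_dir
    out.mkdir(parents=True, exist_ok=True)
    series, schedules, diaries, clinical = _load_inputs(cfg)

    log.info("stage=metrics seed=%d n=%d", cfg.seed, len(series))
    metrics_df, night_rows, table = derive_cohort(
        series, schedules, diaries, clinical, cfg.schema,
        scoring_threshold=cfg.scoring_threshold,
    )
    metrics_df.to_csv(out / "metrics.csv")
    pd.DataFrame(night_rows).to_csv(out / "sleep_nights.csv", index=False)
    log.info("stage=assemble seed=%d", cfg.seed)
    feat_csv = table.X.copy()
    feat_csv.insert(0, "survival_days", table.time)
    feat_csv.insert(1, "event", table.event)
    feat_csv.to_csv(out / "features.csv", index_label="participant_id")
    pd.DataFrame(table.imputation_log).to_csv(out / "imputation_log.csv", index=False)

    log.info("stage=univariate seed=%d", cfg.seed)
    uni_report = univariate_battery(metrics_df, table, series, schedules, out)

    report = {
        "seed": cfg.seed,
        "n_participants": table.n,
        "n_predictors": table.p,
        "n_events": int(table.event.sum()),
        "univariate": uni_report,
        "models": {},
    }
    for name, alpha in cfg.alphas.items():
        log.info("stage=fit model=%s alpha=%.2f seed=%d", name, alpha, cfg.seed)
        report["models"][name] = fit_stage(
            table, name, alpha, out / "models" / name,
            folds=cfg.folds, inner_folds=cfg.inner_folds,
            seed=stage_seed(cfg.seed, "fit"),
        )

    report = _jsonable(report)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def univariate_battery(metrics_df, table: FeatureTable, series, schedules, out_dir=None) -> dict:
    """ICC stability, Spearman variant correlations and the log-rank split battery."""
    rep = {}
    ids = [i for i in table.ids if i in metrics_df.index]
    time = pd.Series(table.time, index=table.ids)
    event = pd.Series(table.event, index=table.ids)

    # I<O day-to-day stability (per-protocol participants, complete daily values)
    daily = {}
    for pid in ids:
        if metrics_df.loc[pid].get("analysis_set") == "per_protocol":
            vals = ra.daily_dichotomy(series[pid], schedules[pid])
            if not np.isnan(vals).any():
                daily[pid] = vals
    if len(daily) >= 2:
        M = np.vstack(list(daily.values()))
        rep["icc_i_less_o"] = uv.icc_stability(M)

    # stability / robustness correlations between I<O variants
    if "i_less_o" in metrics_df.columns:
        sub = metrics_df.dropna(subset=["i_less_o"])
        variants = {}
        for pid in sub.index:
            s, sch = series[pid], schedules[pid]
            n_days = len(s) // ra.MINUTES_PER_DAY
            row = {"full": sub.loc[pid, "i_less_o"], "h20": sub.loc[pid, "i_less_o_20h"]}
            try:
                row["first72"] = ra.dichotomy_index(
                    s, sch, epoch_mask=ra.day_window_mask(s, [0, 1, 2])
                )
                row["weekday"] = ra.dichotomy_index(s, sch, epoch_mask=ra.weekday_mask(s))
                row["weekend"] = ra.dichotomy_index(
                    s, sch, epoch_mask=ra.weekday_mask(s, weekend=True)
                )
            except RestwatchError:
                continue
            variants[pid] = row
        vdf = pd.DataFrame.from_dict(variants, orient="index").dropna()
        if len(vdf) >= 3:
            rep["spearman_72h_vs_full"] = vars(uv.spearman_band(vdf["first72"], vdf["full"]))
            rep["spearman_weekday_weekend"] = vars(uv.spearman_band(vdf["weekday"], vdf["weekend"]))
            rep["spearman_24h_vs_20h"] = vars(uv.spearman_band(vdf["full"], vdf["h20"]))
        for other in ("r24", "mda", "wake_activity"):
            pair = sub.dropna(subset=[other])
            if len(pair) >= 3:
                rep[f"spearman_i_less_o_vs_{other}"] = vars(
                    uv.spearman_band(pair["i_less_o"], pair[other])
                )

    # log-rank split battery
    splits = {}
    def try_split(key, values_s, rule, boundary=None, op=">="):
        joined = values_s.dropna()
        common = [i for i in joined.index if i in time.index]
        if len(common) < 4 or event[common].sum() < 1:
            return
        try:
            res = uv.split_and_test(
                time[common].to_numpy(), event[common].to_numpy(),
                joined[common].to_numpy(), rule, boundary=boundary, op=op,
            )
        except DegenerateSplit:
            return
        splits[key] = {"statistic": res["statistic"], "p": res["p"], "rule": rule,
                       "group_sizes": res["group_sizes"]}

    if "i_less_o" in metrics_df.columns:
        try_split("i_less_o_median", metrics_df["i_less_o"], "median")
        try_split("i_less_o_quartiles", metrics_df["i_less_o"], "quartiles")
        try_split("r24_median", metrics_df["r24"], "median")
        try_split("r24_quartiles", metrics_df["r24"], "quartiles")
    for feat, (op, boundary) in uv.NORMATIVE_SPLITS.items():
        if feat in table.X.columns:
            try_split(feat + "_cutoff", table.X[feat], "cutoff", boundary=boundary, op=op)
    for feat in ("act_tib", "act_na"):
        if feat in table.X.columns:
            try_split(feat + "_median", table.X[feat], "median")
    rep["splits"] = splits

    if out_dir is not None:
        with open(pathlib.Path(out_dir) / "univariate.json", "w") as fh:
            json.dump(_jsonable(rep), fh, indent=2, sort_keys=True)
    return rep


def fit_stage(table: FeatureTable, name: str, alpha: float, out_dir,
              folds=10, inner_folds=5, seed=0) -> dict:
    """One model's out-of-fold hazards, evaluation statistics and output tables."""
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    constant = table.X.columns[table.X.std(axis=0, ddof=0) == 0].tolist()
    if constant:
        log.info("model=%s dropping %d zero-variance predictors: %s",
                 name, len(constant), constant)
        table = FeatureTable.from_arrays(
            table.X.drop(columns=constant).to_numpy(), table.time, table.event,
            names=[c for c in table.X.columns if c not in constant], ids=table.ids,
        )
    cv = out_of_fold_hazards(table, alpha, folds=folds, seed=seed, inner_folds=inner_folds)
    km = km_median_split_eval(cv.hazards.to_numpy(), table.time, table.event)
    corr = hazard_survival_correlation(cv.hazards.to_numpy(), table.time)

    from .survival_models import fit_penalised_cox  # full-data coefficients

    fit = fit_penalised_cox(table, alpha, folds=folds, seed=seed)
    coef_df = pd.DataFrame(
        {
            "variable": fit.coef.index,
            "coefficient": fit.coef.to_numpy(),
            "coefficient_standardised": fit.coef_std.to_numpy(),
            "selection_count": cv.selection_count.reindex(fit.coef.index).to_numpy(),
        }
    )
    coef_df.to_csv(out / "coefficients.csv", index=False)
    pd.DataFrame(
        {
            "participant_id": cv.hazards.index,
            "oof_hazard": cv.hazards.to_numpy(),
            "final_model_hazard": cv.final_hazards.to_numpy(),
            "fold": [cv.fold_of[i] for i in cv.hazards.index],
        }
    ).to_csv(out / "hazards.csv", index=False)
    km["curves"].to_csv(out / "km_curves.csv", index=False)

    section = {
        "alpha": alpha,
        "lambda_min": fit.lambda_min,
        "n_nonzero": int((fit.coef_std != 0).sum()),
        "nonzero_variables": fit.nonzero_set,
        "consistently_selected": cv.consistently_selected,
        "n_consistently_selected": len(cv.consistently_selected),
        "median_oof_hazard": float(np.median(cv.hazards)),
        "log_rank_statistic": km["statistic"],
        "log_rank_p": km["p"],
        "pearson_r": corr["r"],
        "pearson_p": corr["p"],
    }
    with open(out / "evaluation.json", "w") as fh:
        json.dump(_jsonable(section), fh, indent=2, sort_keys=True)
    return section
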