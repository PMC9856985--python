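"""Build the participants x predictors matrix joined to the survival outcome.

Variable typing and encoding follow the study conventions: binary variables
become 0/1 dummies, ordinal variables keep their rank order as integers
(non-numeric ordinal levels get the instrument-declared ranking), clock times
go onto the 12:00->36:00 axis as decimal hours, and continuous variables pass
through. Missing values are filled first from a declared subjective/objective
twin (e.g. actigraphy SE from diary SE), then with the cohort mean; ordinal
imputations round to the nearest valid rank. Observed values are never
altered.

The default schema enumerates 66 predictors: demographics, ECOG-PS
(clinician and patient, day 0 and day 8), PiPS-B items, mGPS, AMTS, the
13-analyte blood panel, MSAS-SF totals, PSQI components and named
disturbance items, opioid use, the four rest-activity metrics, eight
actigraphy sleep parameters and eleven diary parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import SchemaError, TooMuchMissingness, UnknownLevel, UnparseableTime
from .io_formats import ClinicalRecord, parse_clock, to_axis_hours

KINDS = ("binary", "categorical_ordinal", "numeric_continuous", "clock_time")

#: instrument-declared frequency order for PSQI disturbance items
PSQI_FREQ_LEVELS = [
    "not during the past month",
    "less than once a week",
    "once or twice a week",
    "three or more times a week",
]


@dataclass
class FeatureSpec:
    name: str
    kind: str
    source: str = "clinical"
    levels: Optional[list] = None  # ordinal/binary level order, low to high
    twin: Optional[str] = None  # subjective/objective partner feature

    def __post_init__(self):
        if self.kind not in KINDS:
            raise SchemaError(f"{self.name}: unknown kind {self.kind!r}")
        if self.kind == "binary" and self.levels is not None and len(self.levels) != 2:
            raise SchemaError(f"{self.name}: binary levels must have length 2")


@dataclass
class FeatureSchema:
    features: list
    ignore: set = field(default_factory=set)

    def __post_init__(self):
        names = [f.name for f in self.features]
        if len(names) != len(set(names)):
            raise SchemaError("duplicate feature names in schema")
        self._by_name = {f.name: f for f in self.features}
        for f in self.features:
            if f.twin is not None and f.twin not in self._by_name:
                raise SchemaError(f"{f.name}: twin {f.twin!r} not in schema")

    def __len__(self) -> int:
        return len(self.features)

    @property
    def names(self) -> list:
        return [f.name for f in self.features]

    def __getitem__(self, name: str) -> FeatureSpec:
        return self._by_name[name]

    def validate_value(self, f: FeatureSpec, value) -> None:
        """Raise on a value outside the feature's declared domain (no encoding)."""
        if f.kind == "categorical_ordinal" and f.levels is not None:
            if _level_index(f, value) is None:
                raise UnknownLevel(f"{f.name}: unknown level {value!r}")
        elif f.kind == "clock_time" and isinstance(value, str):
            parse_clock(value)  # raises UnparseableTime

    @classmethod
    def from_yaml(cls, path) -> "FeatureSchema":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        feats = [
            FeatureSpec(
                name=item["name"],
                kind=item["kind"],
                source=item.get("source", "clinical"),
                levels=item.get("levels"),
                twin=item.get("twin"),
            )
            for item in doc["features"]
        ]
        return cls(features=feats, ignore=set(doc.get("ignore", [])))

    def to_yaml(self, path) -> None:
        doc = {
            "features": [
                {
                    k: v
                    for k, v in {
                        "name": f.name,
                        "kind": f.kind,
                        "source": f.source,
                        "levels": f.levels,
                        "twin": f.twin,
                    }.items()
                    if v is not None
                }
                for f in self.features
            ],
            "ignore": sorted(self.ignore),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


def default_schema() -> FeatureSchema:
    """The shipped 66-predictor schema covering every variable named in the study."""
    f = []
    add = f.append
    C, O, B, T = "numeric_continuous", "categorical_ordinal", "binary", "clock_time"

    # demographics / clinical background
    add(FeatureSpec("age", C))
    add(FeatureSpec("sex", B, levels=["female", "male"]))
    add(FeatureSpec("months_since_diagnosis", C))
    add(FeatureSpec("bmi", C))
    # performance status, clinician and patient, day 0 and day 8
    for name in ("ecog_clinician_day0", "ecog_patient_day0", "ecog_clinician_day8", "ecog_patient_day8"):
        add(FeatureSpec(name, O))
    # PiPS-B items
    add(FeatureSpec("pips_clinician_survival_estimate", O, levels=["days", "weeks", "months", "year+"]))
    add(FeatureSpec("pips_global_health", O))
    add(FeatureSpec("pulse", C))
    add(FeatureSpec("mgps", O))
    add(FeatureSpec("amts", O))
    add(FeatureSpec("opioid_use", B, levels=["no", "yes"]))
    # venous blood panel
    for name in (
        "haemoglobin", "wbc", "neutrophils", "lymphocytes", "platelets",
        "sodium", "potassium", "urea", "creatinine", "albumin", "alt", "alp", "crp",
    ):
        add(FeatureSpec(name, C))
    # MSAS-SF totals
    for name in ("msas_total", "msas_global_distress", "msas_physical", "msas_psych"):
        add(FeatureSpec(name, C, source="clinical"))
    # PSQI components and named disturbance items
    for name in (
        "psqi_subjective_sleep_quality", "psqi_sleep_latency", "psqi_sleep_duration",
        "psqi_habitual_efficiency", "psqi_sleep_disturbance", "psqi_sleep_medication",
        "psqi_daytime_dysfunction",
    ):
        add(FeatureSpec(name, O, source="psqi"))
    add(FeatureSpec("psqi_usual_bed_time", T, source="psqi"))
    add(FeatureSpec("psqi_usual_getup_time", T, source="psqi"))
    for name in ("psqi_disturb_wake_night", "psqi_disturb_pain", "psqi_disturb_cannot_breathe"):
        add(FeatureSpec(name, O, source="psqi", levels=list(PSQI_FREQ_LEVELS)))
    # rest-activity metrics
    for name in ("i_less_o", "r24", "mda", "wake_activity"):
        add(FeatureSpec(name, C, source="actigraphy"))
    # actigraphy sleep parameters (twinned with diary)
    add(FeatureSpec("act_bt", T, source="actigraphy", twin="diary_bt"))
    add(FeatureSpec("act_gut", T, source="actigraphy", twin="diary_gut"))
    for name in ("tib", "sol", "tst", "se", "waso", "na"):
        add(FeatureSpec(f"act_{name}", C, source="actigraphy", twin=f"diary_{name}"))
    # sleep-diary parameters
    add(FeatureSpec("diary_bt", T, source="sleep_diary", twin="act_bt"))
    add(FeatureSpec("diary_gut", T, source="sleep_diary", twin="act_gut"))
    add(FeatureSpec("diary_time_tried_sleep", T, source="sleep_diary"))
    add(FeatureSpec("diary_final_awakening", T, source="sleep_diary"))
    for name in ("tib", "sol", "tst", "se", "waso", "na"):
        add(FeatureSpec(f"diary_{name}", C, source="sleep_diary", twin=f"act_{name}"))
    add(FeatureSpec("diary_twak", C, source="sleep_diary"))

    schema = FeatureSchema(features=f)
    assert len(schema) == 66, f"default schema has {len(schema)} predictors"
    return schema


# ---------------------------------------------------------------------------
# encoding
# ---------------------------------------------------------------------------

def _level_index(f: FeatureSpec, value) -> Optional[int]:
    levels = f.levels
    for i, lv in enumerate(levels):
        if value == lv or str(value).strip().lower() == str(lv).lower():
            return i
    return None


_BINARY_SYNONYMS = {"yes": 1, "no": 0, "true": 1, "false": 0, "1": 1, "0": 0}


def encode_value(f: FeatureSpec, value) -> float:
    """Encode one raw value as a float per the feature's kind."""
    if f.kind == "binary":
        if f.levels is not None:
            idx = _level_index(f, value)
            if idx is not None:
                return float(idx)
        s = str(value).strip().lower()
        if s in _BINARY_SYNONYMS:
            return float(_BINARY_SYNONYMS[s])
        raise UnknownLevel(f"{f.name}: cannot encode binary value {value!r}")
    if f.kind == "categorical_ordinal":
        if f.levels is not None:
            idx = _level_index(f, value)
            if idx is None:
                raise UnknownLevel(f"{f.name}: unknown level {value!r}")
            return float(idx)
        try:
            v = float(value)
        except (TypeError, ValueError) as exc:
            raise UnknownLevel(f"{f.name}: non-numeric ordinal {value!r} without levels") from exc
        if v != round(v):
            raise UnknownLevel(f"{f.name}: ordinal value {value!r} is not an integer rank")
        return v
    if f.kind == "clock_time":
        if isinstance(value, str):
            m = parse_clock(value)
            if m is None:
                raise UnparseableTime(f"{f.name}: blank clock time")
        else:
            m = float(value)  # minutes since midnight
            if not (0 <= m < 1440):
                raise UnparseableTime(f"{f.name}: clock minutes {value!r} out of [0, 1440)")
        return to_axis_hours(m)
    # numeric_continuous
    return float(value)


def encode_row(values: dict, schema: FeatureSchema):
    """Encode one participant's raw values into (row, missing_mask) arrays."""
    row = np.full(len(schema), np.nan)
    missing = np.zeros(len(schema), dtype=bool)
    for j, f in enumerate(schema.features):
        v = values.get(f.name)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            missing[j] = True
        else:
            row[j] = encode_value(f, v)
    return row, missing


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------

def impute(
    X: pd.DataFrame,
    schema: FeatureSchema,
    max_missing_frac: float = 0.25,
):
    """Fill missing entries: twin value first, then cohort mean.

    Ordinal imputations are rounded to the nearest valid rank. Returns the
    filled copy and a log of (participant, feature, method, value) entries.
    Raises :class:`TooMuchMissingness` when a feature exceeds the cap before
    imputation.
    """
    frac = X.isna().mean()
    over = frac[frac > max_missing_frac]
    if len(over):
        worst = over.index[0]
        raise TooMuchMissingness(
            f"{worst}: {over.iloc[0]:.0%} missing exceeds cap {max_missing_frac:.0%}"
        )
    out = X.copy()
    log = []
    # pass 1: subjective/objective twins (same participant, already encoded —
    # twinned pairs share units by construction of the schema)
    for f in schema.features:
        if f.twin is None:
            continue
        gaps = out.index[out[f.name].isna() & out[f.twin].notna()]
        for pid in gaps:
            val = out.at[pid, f.twin]
            out.at[pid, f.name] = val
            log.append({"participant_id": pid, "feature": f.name, "method": "twin", "value": val})
    # pass 2: cohort mean
    for f in schema.features:
        col = out[f.name]
        if not col.isna().any():
            continue
        observed = col.dropna()
        if observed.empty:
            raise TooMuchMissingness(f"{f.name}: 100% missing, cannot impute")
        val = float(observed.mean())
        if f.kind in ("categorical_ordinal", "binary"):
            val = float(np.round(val))
            if f.levels is not None:
                val = float(np.clip(val, 0, len(f.levels) - 1))
        for pid in out.index[col.isna()]:
            out.at[pid, f.name] = val
            log.append({"participant_id": pid, "feature": f.name, "method": "mean", "value": val})
    return out, log


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

@dataclass
class FeatureTable:
    """Encoded n x p matrix with the survival outcome and pre-imputation mask."""

    ids: list
    X: pd.DataFrame  # n x p, float, no missing values
    time: np.ndarray
    event: np.ndarray
    missing_mask: pd.DataFrame
    imputation_log: list = field(default_factory=list)

    def __post_init__(self):
        if self.X.isna().any().any():
            raise SchemaError("FeatureTable must be complete after imputation")
        if len(self.ids) == 0:
            raise SchemaError("empty feature table")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @classmethod
    def from_arrays(cls, X, time, event, names=None, ids=None) -> "FeatureTable":
        X = np.asarray(X, dtype=float)
        n, p = X.shape
        names = list(names) if names is not None else [f"x{j}" for j in range(p)]
        ids = list(ids) if ids is not None else [f"P{i:03d}" for i in range(n)]
        df = pd.DataFrame(X, index=ids, columns=names)
        return cls(
            ids=ids,
            X=df,
            time=np.asarray(time, dtype=float),
            event=np.asarray(event, dtype=int),
            missing_mask=pd.DataFrame(False, index=ids, columns=names),
        )


def assemble(
    records: Sequence[ClinicalRecord],
    derived: Optional[pd.DataFrame],
    schema: FeatureSchema,
    max_missing_frac: float = 0.25,
) -> FeatureTable:
    """Encode, join and impute the full machine-learning table.

    ``derived`` holds per-participant actigraphy/diary-derived raw values
    (indexed by participant id, columns named as in the schema); clinical raw
    values come from the records. Derived values override nothing — a feature
    is taken from whichever source provides it, clinical first.
    """
    rows, masks, ids, times, events = [], [], [], [], []
    for rec in records:
        values = dict(rec.values)
        if derived is not None and rec.participant_id in derived.index:
            for k, v in derived.loc[rec.participant_id].items():
                if k not in values or values[k] is None:
                    values[k] = None if (isinstance(v, float) and np.isnan(v)) else v
        row, miss = encode_row(values, schema)
        rows.append(row)
        masks.append(miss)
        ids.append(rec.participant_id)
        times.append(rec.survival_days)
        events.append(rec.event)

    X = pd.DataFrame(np.vstack(rows), index=ids, columns=schema.names)
    mask = pd.DataFrame(np.vstack(masks), index=ids, columns=schema.names)
    filled, log = impute(X, schema, max_missing_frac=max_missing_frac)
    return FeatureTable(
        ids=ids,
        X=filled,
        time=np.asarray(times, dtype=float),
        event=np.asarray(events, dtype=int),
        missing_mask=mask,
        imputation_log=log,
    )
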