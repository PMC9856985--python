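"""Univariate survival machinery: KM curves, log-rank splits, Spearman bands, ICC.

Implements the study's univariate toolkit: Kaplan-Meier estimation with
median / quartile / normative-cut-off group splits tested by the log-rank
test, Spearman rank correlations reported with the interpretation bands
(negligible < 0.3 <= low < 0.5 <= moderate < 0.7 <= high < 0.9 <= very
high, applied to |r|), and the intraclass correlation coefficient used to
assess day-to-day stability of the dichotomy index.

The ICC is the two-way mixed-effects, single-measure, consistency form
ICC(3,1) by default — days act as fixed raters in a stability design — with
the absolute-agreement random-rater form ICC(2,1) selectable. The 95% CI
uses the standard F-distribution interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .errors import DegenerateSplit, IncompleteMatrix, NoEvents, ZeroVariance

#: lower bounds of the |r| interpretation bands, boundary values land upward
SPEARMAN_BANDS = [
    (0.9, "very high"),
    (0.7, "high"),
    (0.5, "moderate"),
    (0.3, "low"),
    (0.0, "negligible"),
]

#: normative cut-offs for the actigraphy sleep-parameter split battery
NORMATIVE_SPLITS = {
    "act_tst": (">=", 390.0),  # >= 6.5 h
    "act_sol": ("<=", 30.0),
    "act_se": (">=", 85.0),
    "act_waso": (">", 30.0),
}


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank
# ---------------------------------------------------------------------------

def km_estimate(time, event) -> pd.DataFrame:
    """Product-limit survival estimate as a (time, survival) step table."""
    km = KaplanMeierFitter()
    km.fit(np.asarray(time, dtype=float), np.asarray(event, dtype=int))
    sf = km.survival_function_
    return pd.DataFrame({"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()})


def log_rank(time, event, groups) -> dict:
    """g-group log-rank test; chi-square statistic with g-1 df, two-sided p."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    groups = np.asarray(groups)
    if event.sum() < 1:
        raise NoEvents("log-rank requires at least one event")
    labels = np.unique(groups)
    if len(labels) < 2:
        raise DegenerateSplit("log-rank requires >= 2 non-empty groups")
    res = multivariate_logrank_test(time, groups, event)
    return {
        "statistic": float(res.test_statistic),
        "p": float(res.p_value),
        "df": len(labels) - 1,
    }


def split_groups(values, rule: str, boundary: Optional[float] = None, op: str = ">=") -> np.ndarray:
    """Group labels under a median / quartiles / cutoff rule.

    median: ties go to the low group (label ``"low"`` for value <= median).
    quartiles: four near-equal groups by rank order (stable sort breaks ties).
    cutoff: two groups by ``value <op> boundary`` with the printed inclusivity.
    """
    v = np.asarray(values, dtype=float)
    if rule == "median":
        med = np.median(v)
        labels = np.where(v > med, "high", "low")
    elif rule == "quartiles":
        order = np.argsort(v, kind="stable")
        labels = np.empty(len(v), dtype=object)
        for q, chunk in enumerate(np.array_split(order, 4)):
            labels[chunk] = f"Q{q + 1}"
    elif rule == "cutoff":
        if boundary is None:
            raise ValueError("cutoff rule needs a boundary")
        ops = {
            ">=": v >= boundary,
            "<=": v <= boundary,
            ">": v > boundary,
            "<": v < boundary,
        }
        if op not in ops:
            raise ValueError(f"unknown comparison {op!r}")
        labels = np.where(ops[op], "meets_cutoff", "outside_cutoff")
    else:
        raise ValueError(f"unknown split rule {rule!r}")
    labels = np.asarray(labels, dtype=object)
    if len(np.unique(labels)) < 2:
        raise DegenerateSplit(f"{rule} split put every participant in one group")
    return labels


def split_and_test(time, event, values, rule: str, boundary: Optional[float] = None,
                   op: str = ">=") -> dict:
    """Form groups by the rule and run the log-rank test."""
    labels = split_groups(values, rule, boundary=boundary, op=op)
    out = log_rank(time, event, labels)
    out["rule"] = rule
    out["groups"] = labels
    out["group_sizes"] = pd.Series(labels).value_counts().to_dict()
    return out


# ---------------------------------------------------------------------------
# Spearman with interpretation bands
# ---------------------------------------------------------------------------

@dataclass
class CorrelationBandReport:
    r: float
    band: str
    p: float
    n: int


def band_label(r: float) -> str:
    a = abs(r)
    for lo, name in SPEARMAN_BANDS:
        if a >= lo:
            return name
    return "negligible"


def spearman_band(x, y) -> CorrelationBandReport:
    """Spearman rank correlation (tie-corrected) with its interpretation band."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ZeroVariance("constant input to Spearman correlation")
    r, p = stats.spearmanr(x, y)
    return CorrelationBandReport(r=float(r), band=band_label(r), p=float(p), n=len(x))


# ---------------------------------------------------------------------------
# ICC
# ---------------------------------------------------------------------------

def icc_stability(matrix, form: str = "icc3", alpha: float = 0.05) -> dict:
    """ICC of a complete subjects x days matrix with a 95% F-interval CI.

    ``form="icc3"``: two-way mixed, consistency, single measure (default);
    ``form="icc2"``: two-way random, absolute agreement, single measure.
    """
    M = np.asarray(matrix, dtype=float)
    if M.ndim != 2 or M.shape[0] < 2 or M.shape[1] < 2:
        raise IncompleteMatrix("need >= 2 subjects and >= 2 days")
    if np.isnan(M).any():
        raise IncompleteMatrix("matrix contains missing cells")
    n, k = M.shape

    grand = M.mean()
    row_means = M.mean(axis=1)
    col_means = M.mean(axis=0)
    ss_total = ((M - grand) ** 2).sum()
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    if form == "icc3":
        icc = (msr - mse) / (msr + (k - 1) * mse)
    elif form == "icc2":
        icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    else:
        raise ValueError(f"unknown ICC form {form!r}")

    # F interval on MSR/MSE (exact for consistency; conventional for icc2)
    df1, df2 = n - 1, (n - 1) * (k - 1)
    fobs = msr / mse
    fl = fobs / stats.f.ppf(1 - alpha / 2, df1, df2)
    fu = fobs * stats.f.ppf(1 - alpha / 2, df2, df1)
    ci = ((fl - 1) / (fl + k - 1), (fu - 1) / (fu + k - 1))
    p = float(stats.f.sf(fobs, df1, df2))
    return {"icc": float(icc), "ci95": (float(ci[0]), float(ci[1])), "p": p,
            "form": form, "n_subjects": n, "n_days": k}
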