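# restwatch

Survival prognostication in advanced cancer from wrist actigraphy, sleep
diaries and routine clinical data.

Patients with advanced cancer often show degraded rest-activity rhythms —
fragmented sleep, low daytime activity — and these behavioural signals may
carry prognostic information beyond the usual clinical predictors
(performance status, inflammatory markers, clinician estimates). `restwatch`
implements, as a tested and reusable pipeline, the analysis needed to test
that idea on a feasibility-study-sized cohort:

1. **Rest-activity metrics** from minute-epoch actigraphy counts:
   the dichotomy index *I<O* (percentage of in-bed activity counts strictly
   below the median out-of-bed count; *I<O* ≤ 97.5% flags a disrupted
   rhythm), the 24-h lag autocorrelation *r24*, mean daily activity (MDA)
   and mean activity during daytime wakefulness — with per-protocol
   (8 consecutive valid 24-h wear periods) and full-analysis (≥ 3)
   qualification rules, and the 20-h restricted, first-72-h and
   weekday/weekend *I<O* variants.
2. **Sleep parameters** per night, from two routes: Actiware-style weighted
   five-epoch sleep/wake scoring of the counts (weights 0.04/0.2/1/0.2/0.04,
   medium sensitivity threshold 40), and consensus-sleep-diary arithmetic
   (TIB = GUT − BT, TWAK = GUT − final awakening,
   TST = TIB − (SOL + WASO + TWAK), SE = 100·TST/TIB).
3. **Feature assembly**: a 66-predictor participants × variables matrix
   (binary dummies, rank-encoded ordinals, clock times on a 12:00→36:00
   axis, continuous pass-through) with twin-first imputation (actigraphy ↔
   diary) and cohort-mean fallback, joined to right-censored survival.
4. **Penalised Cox models** at the three study mixing parameters — ridge
   (α = 0.01), elastic net (α = 0.5), lasso (α = 0.99) — with the penalty
   λ·(α‖β‖₁ + (1−α)/2·‖β‖₂²) on standardised coefficients, λ chosen by
   minimum mean cross-validated partial-likelihood deviance (CVM) over a
   100-point path, out-of-fold hazards exp(xᵀβ̂) from 10-fold refits that are
   fully blind to the held-out participant, selection-consistency counts,
   Kaplan–Meier median-hazard splits with log-rank tests, and the Pearson
   correlation between predicted hazard and observed survival days.
5. **Univariate machinery**: KM estimation, log-rank split batteries
   (median, quartiles, normative cut-offs TST ≥ 6.5 h, SOL ≤ 30 min,
   SE ≥ 85%, WASO > 30 min), Spearman correlations with interpretation
   bands, and ICC(3,1) day-to-day stability of *I<O*.
6. **A synthetic cohort generator** with known ground truth (two-state
   semi-Markov activity with a fragmentation parameter, negative-binomial
   counts, diaries correlated with actigraphy, frailty-linked clinical
   covariates, exponential survival with administrative censoring) so the
   whole pipeline is testable without any participant data.

## Worked example

```bash
restwatch run --simulate --n 50 --seed 1 --out runs/demo
```

simulates the default 50-participant, 8-day cohort, derives all metrics,
assembles the 66-predictor table and fits the three models. It prints:

```json
{
  "elastic_net": {"log_rank_p": 1.127e-08, "n_nonzero": 25, "pearson_r": -0.398},
  "lasso":       {"log_rank_p": 7.294e-07, "n_nonzero": 12, "pearson_r": -0.358},
  "ridge":       {"log_rank_p": 1.853e-09, "n_nonzero": 59, "pearson_r": -0.369}
}
```

(values rounded; the full-precision report is written to `runs/demo/report.json`)

`n_nonzero` is the number of predictors with non-zero coefficient at the
CVM-minimising λ (the lasso is sparse, the ridge keeps nearly everything);
`log_rank_p` tests whether splitting participants at the median out-of-fold
hazard separates their survival curves; `pearson_r` is the correlation
between predicted hazard and observed survival days (negative: higher
predicted hazard, shorter survival). Full outputs — per-participant metrics,
per-night sleep parameters, coefficient and selection-consistency tables,
hazards, KM curve coordinates, the univariate battery — are written under
`runs/demo/`.

The same stages are available individually (`restwatch simulate`,
`metrics`, `sleep`, `fit`) and as library functions (`restwatch.dichotomy_index`,
`restwatch.fit_penalised_cox`, ...).

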