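# Methods

This note records the models, conventions and numerical choices behind
`restwatch`, and what the synthetic-data tests do and do not demonstrate.

## Rest-activity metrics

**Dichotomy index I<O.** For one participant, pool every non-missing
out-of-bed epoch count across the qualifying recording and take its median
*m*; I<O is 100 × (number of in-bed epochs with count strictly below *m*) /
(number of non-missing in-bed epochs). Two conventions are deliberate and
exposed as flags:

* *strictness* — "inferior to the median" is strict `<`; epochs exactly
  equal to *m* do not count (`strict=False` switches to `<=` for
  sensitivity analysis);
* *pooled median* — one median over the whole recording, not per-day; the
  published I<O convention names a single median.

I<O depends only on the order statistics of the counts, so it is invariant
under strictly increasing transformations — exactly so whenever the
out-of-bed pool has odd size (the even case interpolates two order
statistics, which a monotone map need not preserve). I<O ≤ 97.5% labels the
rest-activity rhythm disrupted. The 20-h restricted variant removes the
hour on either side of each in-bed boundary from both pools before
computing, reflecting uncertainty about reported bed/rise times.

**r24** is the Pearson autocorrelation of the raw count series at a lag of
1440 one-minute epochs, with pairwise deletion of missing epochs; at least
1440 valid pairs (≥ 48 h of usable data) are required. Counts are not
smoothed, detrended or zero-filled; missingness is never imputed at this
stage.

**MDA** is the arithmetic mean of non-missing counts over the full
recording; **wake activity** is the mean over epochs strictly between
consecutive in-bed intervals.

**Analysis sets.** A 24-h wear block (1440 epochs from recording start) is
*valid* when ≥ 90% of its epochs are non-missing (threshold configurable;
no published validity rule exists, so one had to be fixed). Blocks are
wear-aligned, not midnight-aligned: participants are fitted with the device
at a daytime review and wear it for consecutive 24-h periods, and the
synthetic recordings start at 12:00 so each block contains one whole night.
Per-protocol = 8 consecutive valid blocks with 8 diary nights;
full-analysis = at least 3 of each; otherwise excluded. Metrics are only
emitted for participants with ≥ 3 consecutive valid blocks.

## Sleep scoring and parameters

The device's published scoring rule is used: each epoch's weighted count
W = 0.04·(c₋₂+c₊₂) + 0.2·(c₋₁+c₊₁) + c₀ is compared with a sensitivity
threshold (default 40 = medium; 20 and 80 selectable), sleep iff
W ≤ threshold. Missing neighbours, and neighbours beyond the recording,
contribute zero weight. Sleep onset is the start of the first run of 10
consecutive sleep-scored minutes (run length configurable); final awakening
is the end of the last such run. TST counts sleep minutes between onset and
final awakening, WASO the wake minutes, NA the number of contiguous wake
blocks in between; TIB is the in-bed interval length and SE = 100·TST/TIB.
Which sensitivity the original device configuration used is not knowable
from the outside, hence the default-plus-options design.

Diary parameters use the consensus-diary arithmetic identity
SOL + WASO + TWAK + TST = TIB, which therefore holds exactly, by
construction, for every non-flagged night; a night whose reported durations
exceed TIB gets TST/SE set missing and flagged rather than clamped to an
invented value.

**Clock times** live internally as minutes since midnight and are ordered
on a 12:00→36:00 axis (times before noon shifted +24 h) so bedtimes
spanning midnight sort correctly; as model features they are encoded as
decimal hours on that axis (07:30 → 31.5). Participant-level aggregates of
bed/get-up times use the circular mean (23:30 and 00:30 average to 00:00).

## Feature table

The 66-predictor schema is config-driven (YAML) with a shipped default
covering demographics, clinician- and patient-assessed ECOG-PS at day 0 and
day 8, PiPS-B items (clinician survival estimate, global health, pulse),
mGPS, AMTS, opioid use, a 13-analyte blood panel, MSAS-SF totals, PSQI
components with named disturbance items and usual bed/get-up times, the
four rest-activity metrics, eight actigraphy sleep parameters and eleven
diary parameters. Binary variables become 0/1; ordinals keep their declared
rank order; non-numeric ordinal levels (PSQI frequency items) are ranked by
the instrument-defined frequency order.

Imputation is twin-first: a missing value with a declared
subjective/objective partner (e.g. actigraphy SE ↔ diary SE) is filled from
the same participant's partner value, the remainder from the cohort mean
(ordinals rounded to the nearest valid rank), with a per-feature missing
cap of 25% and a complete imputation log. Observed values are never
altered. Whether the original "group average" meant the whole cohort or a
subgroup is not stated anywhere; the whole cohort is used.

## Penalised Cox models

Predictors are standardised (zero mean, unit variance) inside the model
fit; coefficients are reported on both scales. The elastic-net Cox path —
penalty λ(α‖β‖₁ + (1−α)/2‖β‖₂²) — is computed by scikit-survival's
coordinate-descent solver over 100 log-spaced λ from λ_max (all
coefficients zero) down to 10⁻³·λ_max. The three mixing parameters are
ridge α = 0.01, elastic net α = 0.5, and lasso α = 0.99 (0.99, not 1.0, is
kept deliberately). When the solver stops a path early (deviance
saturation) the last reached solution is carried to the remaining smaller
λ, the path-software convention.

**CVM** is the Verweij–van Houwelingen cross-validated partial-likelihood
deviance: for fold k, −2·[ℓ(all; β₍₋ₖ₎) − ℓ(train_k; β₍₋ₖ₎)] with Breslow
ties, summed over folds and divided by the total number of events; λ_min
minimises it over the grid ("exhaustive search" = grid search). Fold
assignment is seeded, stratified by event status so every training set
contains events, and keyed on sorted participant ids, making it invariant
to input row order.

**Out-of-fold hazards.** Each participant's relative hazard exp(xᵀβ̂) comes
from the model fit on the other k−1 folds (k = 10 by default), with λ
re-selected by an inner cross-validation (5 inner folds) on the training
folds only and standardisation statistics computed on the training folds
only — the prediction is fully blind to the participant. A column constant
within a training fold is dropped from that fold's model (it carries no
information there). "Consistently selected" = non-zero in all k fold
refits. Because the published description also mentions a final model built
on all subjects, the non-blind final-model hazards are emitted alongside,
clearly labelled; all evaluation statistics use the blind ones.

**Evaluation.** Participants are split at the median out-of-fold hazard
(ties to the low-hazard group), KM curves per group are compared by the
two-group log-rank test (standard hypergeometric variance, no continuity
correction), and the Pearson correlation between predicted hazard and
observed survival days is reported with censored participants entering at
their censoring time (whether they should instead be excluded is
undocumented; including them is the literal reading of "actual survival in
days" for a cohort followed to an administrative cut-off).

## Univariate machinery

KM estimation and log-rank tests delegate to lifelines. Split rules:
median (ties low), quartiles (four near-equal groups by stable rank order —
the boundary convention for quartile splits is not documented anywhere, so
rank-order assignment was chosen for determinism under ties), and normative
cut-offs with the printed inclusivity (TST ≥ 390 min, SOL ≤ 30 min,
SE ≥ 85%, WASO > 30 min). No multiple-testing correction is applied across
the battery, deliberately mirroring the original analysis; this is a known
limitation, noted rather than silently fixed.

Spearman correlations are tie-corrected and reported with interpretation
bands on |r|: negligible < 0.3 ≤ low < 0.5 ≤ moderate < 0.7 ≤ high < 0.9 ≤
very high (boundary values land in the upper band).

The ICC is computed from the two-way ANOVA mean squares;
ICC(3,1) — two-way mixed, consistency, single measure — is the default
because recording days act as fixed "raters" in a stability design, with
ICC(2,1) selectable. The 95% CI uses the standard F interval on MSR/MSE.

## Synthetic cohort generator

The generator defines the study conditions for every test: n = 50
participants, 8 days of 1-min epochs starting at 12:00, one in-bed interval
per night (≈ 23:00–07:00 ± 20 min), a diary per night, 66 predictors,
administrative censoring at day 365.

Activity is a two-state semi-Markov process: outside scheduled nights the
participant is awake; inside the night, sleep-onset latency and terminal
wakefulness scale with a fragmentation parameter ρ (per-minute wake-bout
initiation probability; bout length 1 + Geometric(0.3) minutes). Counts are
negative-binomial (size 1.5 — wrist counts are overdispersed) with state
means: asleep 3 counts/min; awake, a 24-h sinusoid around a daytime mean
(base 250 counts/min, amplitude 0.3–0.7, peak ≈ 15:00). A latent frailty
(standard normal) raises ρ and lowers the daytime mean, so I<O falls with
frailty by construction, and the same frailty enters the survival hazard.
ρ ranges over (0.005, 0.14), calibrated once so the generated I<O
distribution matches the published cohort statistics (mean ≈ 89%, median
≈ 90%, nearly all participants ≤ 97.5%).

Diaries are truth plus zero-mean reporting noise (clock times ± 10 min SD,
durations ± 15% CV), clamped so the diary identity remains satisfiable;
with both noise scales at zero the diary equals the truth exactly.

Clinical covariates mix frailty-linked ordinals and blood values (so the
encoded table shows realistic collinearity) with independent noise
variables. Survival is exponential — chosen over Weibull for closed-form
checkability — with rate λ₀·exp(zᵀβ_true + 0.4·frailty), where z are the
standardised encoded clinical covariates, β_true is a sparse 10-variable
vector (harmful: CRP, urea, creatinine, neutrophils, ECOG, opioid use, poor
subjective sleep; protective: clinician survival estimate, global health,
haemoglobin), and λ₀ = ln 2 / 110 per day, set so ≈ 68% of participants
die before the day-365 cut-off, the published cohort's one-year mortality.
A `strong_signal_spec` preset doubles the effect sizes for power and
recovery experiments.

**What passing tests show and do not show.** The generator reproduces the
*structure* of the study data (epoch grid, schedules, diary identity,
variable types, censoring, collinearity, frailty-driven links between
actigraphy and survival) but not device artefacts (off-wrist noise,
autocorrelated counts within a state, napping), non-proportional hazards,
informative censoring, or the true joint distribution of the clinical
variables. Tests passing on it validate the pipeline's arithmetic and the
models' behaviour under a known truth; they do not certify predictive
performance on real patients.

## Problem sizes and determinism

Every stochastic component is seeded; one global seed expands
deterministically into per-stage seeds (`SeedSequence([seed, stage])`), and
cohort generation spawns one child stream per participant, so outputs are
bit-reproducible and invariant to participant order. The shipped test suite
uses: 200 random instances for the I<O oracle check, 1000 random diaries
for the identity check, 50 seeds at n = 300 for lasso support recovery,
2000 null simulations at n = 40 for log-rank calibration, 100 replicates of
50 × 8 matrices for ICC recovery, and 20 seeds of the strong-signal
50-participant cohort for the end-to-end power check.

## Known limitations

* Off-wrist handling is a policy flag (treat-missing vs exclude) because
  the original handling is undocumented; both reduce to missing epochs in
  the current metrics.
* The exact identity of the original 66 predictors is not fully published;
  the default schema covers every named variable and the count, but
  individual items may differ.
* The quartile-split boundary convention and the censored-participant
  handling in the hazard–survival correlation are undocumented originals;
  the choices here are stated above and flagged in code.
* Nap detection outside the major sleep period, cosinor rhythm fitting and
  nonparametric IS/IV statistics are out of scope.
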