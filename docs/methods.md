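# Methods

This note documents the models, conventions, and design choices behind
`cdewatch`, in the order the pipeline runs. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Cohort and event construction

**Admission merging.** PICU stays within one hospital encounter separated
by a PICU-absence gap under 24 h are one clinical admission; the merged
record spans the earliest start to the latest end and keeps the first
stay's demographics. Overlapping stays within an encounter are a data
error and rejected. Merging is idempotent.

**Inclusion.** Admissions with stay ≥ 24 h and age in [0, 25) years are
retained. The age bound is read inclusively through the 25th year
(24.999… y retained) because a cohort described as 0–24 years that
explicitly includes 22–24-year-olds is using age-at-last-birthday.
Duration is applied before age when attributing exclusion counts to the
flowchart record.

**Unplanned intubation (UEI).** An intubation counts as a deterioration
event iff it persisted ≥ 48 h (elective and procedural airway management
is briefer). An intubation still ongoing at discharge or death is
confirmed regardless of elapsed time — the stay end censors persistence
and deterioration is presumed — and flagged `ongoing_at_end` so
sensitivity analyses can drop it. An extubation time before the
intubation is a validation error. If a `planned` flag is present in the
raw events it excludes the row before the persistence rule is applied.

**Deduplication.** Events within 8 h of a prior event in the same
admission belong to the same deterioration trajectory (e.g., ECMO
cannulation during CPR) and are suppressed by a single chronological
greedy pass. The 8-h lockout anchors on the last *kept* event by default:
events at t, t+5 h, t+9 h keep t and t+9 h. The alternative convention
(re-anchor on every raw event, so the run t, t+5, t+9 keeps only t) is
available via `anchor_on_kept=False`. The boundary is closed at 8 h: a
gap of exactly 8 h keeps both events.

**Temporal split.** Development = PICU start before the boundary date;
validation = PICU start *and* hospital-encounter start on or after it.
Straddlers (admitted to the PICU after the boundary during an encounter
that began before it) are excluded from both sets: they are not
development-period admissions, and including them in validation would
leak development-period context.

**Training samples.** Each confirmed event at time *e* (beyond the first
16 h of the admission) yields one positive snapshot per horizon at
*e* − *h*, *h* ∈ {1, 2, 4, 6, 8, 12}. Events in the first 16 h never
become training targets (baseline data availability), and an admission
whose only events are that early contributes nothing. Each event-free
admission yields exactly one control snapshot drawn uniformly at 1-minute
resolution from the closed window [start + 16 h, end − 6 h], shared
across the six horizon models (drawing per-horizon controls would only
inflate the control correlation between members). Per-admission draws
come from independent streams hashed from (seed, admission id, purpose),
so editing one admission never reshuffles another.

All timestamps are timezone-naive at minute resolution; durations are
computed in minutes and reported in hours.

## Snapshot features

For every numeric variable (vitals, labs) and lookback window *w*:
last value, mean, min, max, least-squares slope per hour, measurement
count, and hours since the last measurement; for every medication and
window: administration count and an any-given flag; plus age (years) and
sex. Windows are half-open (*t* − *w*, *t*]: an observation exactly at
the snapshot is included, one exactly *w* hours earlier is not. Slope
needs ≥ 2 distinct timestamps, else missing; duplicate timestamps keep
the last-recorded value. Missing summaries are NaN — the default
gradient-boosted learner routes missingness natively, and the other
families sit behind a median imputer; no imputation is done in the
feature layer. Unknown variable names in a stream are ignored with a
logged warning.

**Default windows are {6, 16} h, deliberately capped at the 16-h
early-exclusion period.** Every training snapshot sits at least 16 h into
its admission, so a ≤ 16-h window is always fully covered by the stay. A
longer window (e.g., 24 h) truncates at admission start for snapshots
before hour 24, making measurement counts and extreme-value summaries
encode *position in stay* rather than physiology; because positive and
control snapshots do not occupy identical position distributions, that
artifact alone produced AUROC ≈ 0.54 on signal-free data during
development. Capping the window at the early-exclusion period removes the
artifact structurally — the same reasoning that motivates excluding the
first 16 h from training in the first place. Windows remain configurable
for users whose sampling design differs.

## Horizon ensemble

One classifier per horizon, trained on that horizon's positives plus the
shared controls. Cross-validation is stratified by label and grouped by
*patient* (stricter than admission-level grouping; an admission-level
flag exists). Hyperparameters are chosen by mean held-out AUROC over 10
folds, ties broken by deterministic grid order; folds shrink with a
warning when there are fewer patients than folds. The default grid is
deliberately small (depth × min-child-weight, 4 combinations) to keep
desk-scale runtime; it is plain configuration. The ensemble probability
is the arithmetic mean of the six member probabilities — order-invariant
and bounded in [0, 1] by construction. Class imbalance is handled only by
the control down-sampling design (one control per event-free admission);
no reweighting.

Parsimonious variants rank features per horizon by plug-in
(maximum-likelihood) mutual information in bits, with continuous features
discretized into 10 equal-frequency bins and NaN as its own bin (so
informative missingness counts). The estimator is biased upward at small
n like all plug-in MI estimators, which is immaterial for ranking. The
per-horizon top-k subsets are retrained; their union (between k and 6k
names) describes the variant's footprint.

Models persist as a JSON envelope (feature schema, horizons, family,
pickled learner blobs); loading revalidates the schema hash.

## Evaluation statistics

AUROC is the midrank Mann–Whitney statistic; AUPRC is average precision
(step-wise interpolation over recall change points). Both delegate to
scikit-learn, which implements exactly these definitions; the test suite
re-derives them by exhaustive pair enumeration and a precision–recall
ladder on every small random instance.

Confidence intervals are percentile intervals from class-stratified
bootstrap resampling (positives and negatives resampled independently;
B = 2000; replicates on which a metric is undefined are redrawn and
logged). Percentile rather than BCa is the default for its minimal
assumptions; the interval level is 95%.

The paired DeLong test compares two models scored on the same samples via
the empirical covariance of midrank placement values; identical models
give zero variance and p = 1 by convention. Subgroup comparisons are a
different problem — two disjoint samples — so they use an unpaired z-test
whose variance is the sum of the two groups' single-model DeLong
variances. Benjamini–Hochberg control runs across the whole family of
subgroup comparisons; subgroups with one outcome class are flagged
not-evaluable and excluded from the family. Operating points pick, for a
sensitivity target s, the largest threshold with sensitivity ≥ s (the
fewest false positives at the required sensitivity) and report
sensitivity, specificity, PPV, and NNA = 1/PPV.

## Alert-burden simulation

The simulator replays a risk series as a deployed system would consume
it. Conventions, each behind a flag or policy field and each pinned by a
test:

* prediction grid: admission start, then every Δ hours, including a
  point at the stay end;
* threshold: fire at probability ≥ θ (so a 0/1 comparator stream at
  θ = 0.5 behaves identically to the generic path); strict `>` by flag;
* refractory: an alert at *a* blocks the open interval (*a*, *a* + *R*);
  the first grid point at or after *a* + *R* is eligible; the period
  re-anchors on every fired alert;
* censoring: each event *e* blocks [*e*, *e* + 24 h); alerts resume
  exactly 24 h after the event;
* detection: event *e* is caught iff an alert exists in [*e* − 24 h, *e*)
  — an alert at the event instant is not advance warning;
* lead time: earliest qualifying alert in the window (maximal preparation
  time); latest by flag;
* patient-day denominator: full stay durations, censored and refractory
  time included (no exclusion is defensible without a stated workflow);
* *all* confirmed events enter the burden analysis, including those in
  the first 16 h of admission — the training-time exclusion does not
  apply to deployment emulation.

Threshold sweeps check monotonicity (burden and detection non-increasing
in θ) as a post-check and *warn* rather than repair: a genuine, rare
violation is possible when a low threshold fires an early alert whose
refractory period swallows the only would-be in-window alert. The
admission-level NNA is flagged admissions per flagged admission with a
detected event — the reciprocal of admission-level PPV.

Correctness is established against a minute-resolution event-loop oracle
(exact agreement on 1000 random instances) and against renewal theory:
on a Δ-grid where each probability independently exceeds θ with
probability q, one alert cycle is the refractory span rounded up to the
grid plus a geometric wait, so the steady-state rate is
24 / (Δ·max(1, ⌈R/Δ⌉) + Δ(1/q − 1)) alerts per patient-day. The
empirical check uses a fixed number (5) of complete inter-alert cycles
per stay: the process regenerates at each alert, making those gaps
i.i.d. cycle draws — unbiased, unlike counting alerts over a fixed
window (start-up edge bias) or averaging all completed gaps
(inspection-paradox truncation, measured at about −4% in the slowest
cells during development). Deterministic cells (q = 1) must match the
closed form exactly.

## Synthetic cohort generator

The generator emulates the *structure* of a single-center PICU cohort,
not its physiology: ~5% of admissions experience an event (configurable);
log-normal stays (median 72 h, σ_log 0.5, floored at 24 h; sub-24-h stays
on request to exercise the inclusion filter); 10% of patients readmit,
half within the same encounter at gaps of 4–48 h (exercising the merge
rule both ways); event types drawn at CPR/ECMO/epinephrine/intubation
proportions of roughly 14/1/33/51%; intubation durations straddle the
48-h rule (30% short) and can run past discharge (ongoing-at-end).
Demographics are sampled from realistic marginals (56% female; neonate
through young-adult age mix) and are independent of events by
construction, so fairness analyses have a true null.

Vitals (HR, RR, SBP, DBP, SpO2; mean 1-h exponential gaps) and labs
(lactate, creatinine, WBC, platelets; mean 8-h gaps) follow baseline +
patient-level shift + continuous-time AR(1) noise (autocorrelation 0.8
per hour). The deterioration signature is a linear drift reaching
δ · (per-variable scale) at the event, beginning τ = 12 h before it, with
a clinically signed direction per variable (tachycardia, desaturation,
hypotension, rising lactate…), relaxing back over 6 h after the event.
Medication streams are Poisson; their pre-event rate multiplier is *part
of the signature* and is disabled when δ = 0, so the null condition is a
true null. A linear (not step) drift gives horizon models graded signal;
note the corollary that with τ equal to the longest horizon the 12-h
member sees essentially zero accumulated drift at its snapshot, so
per-horizon discrimination rises steeply toward short horizons.

Event times are uniform over [28 h, stay − 2 h]. The lower bound is the
16-h training exclusion plus the longest (12-h) horizon, so every
positive snapshot shares the controls' support ([16 h, stay)); allowing
earlier events would let position-in-stay, not physiology, separate the
classes and would break the δ = 0 chance-level property the end-to-end
tests rely on.

**What passing tests show — and do not.** The end-to-end recovery test
(1000 patients, δ = 3, τ = 12 h → validation AUROC > 0.85; δ = 0 →
AUROC in [0.45, 0.55]) demonstrates that the pipeline extracts a known
signal without leaking one that is not there. The δ = 0 control is run
at a 30% event rate so the null band is measured on > 2000 samples
(~250 event-admission clusters); at the study's 5% rate the
cluster-level Monte-Carlo error alone exceeds the band's width. None of
this says anything about real EHR data: the generator has no documentation
artifacts, no treatment feedback, no unit-practice drift, and its
missingness is benign (sampling gaps, not informative absence).

## Problem sizes and numerical choices

Default test and acceptance scales — 1000-patient cohorts for parameter
recovery, 500 stays per renewal cell, 1000 replicates for the simulator
oracle, DeLong calibration, and metric brute-force suites — were chosen
as the smallest sizes at which the checked bands are comfortably wider
than Monte-Carlo error. Floating-point comparisons in tests use exact
equality where the computation is exact (simulator vs. oracle, BH vs.
direct definition) and documented statistical bands elsewhere. Ties in
MI ranking and CV model selection break by stable ordering, making every
seeded run bit-reproducible.

## Known limitations

* The feature scheme is this package's own fully-specified stand-in for a
  production feature dictionary; no clinical vocabulary normalization,
  unit conversion, or artifact filtering is attempted.
* No calibration layer or calibration metrics; the risk index is used
  only for ranking and thresholding.
* The alert simulation cannot represent feedback: real alerts change
  clinician behavior and subsequent documentation.
* SHAP-style attribution is out of scope (the ensemble object is pickled
  and can be handed to external explainers).
* The admission-level NNA is reported for comparability with prior
  practice; alerts per patient-day is the better burden measure, which is
  the point of the toolkit.
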