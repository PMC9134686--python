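# Methods

## The simulated multi-database world

Every synthetic database is drawn from one shared outcome-generating
logistic model

    P(y_j = 1 | x) = expit(beta0_j + delta_k + x · beta),

where `x` is a binary design vector (condition/drug indicators, 5-year
age-bin indicators, a male indicator), `beta` is common to all databases,
`beta0_j` sets the base rate of outcome `j`, and `delta_k` is a
database-specific intercept shift. Heterogeneity between databases enters
through three channels only:

1. **Age structure.** Ages are truncated-normal per database. The default
   five-database scenario uses mean ages (41, 35, 75, 50, 49) years with SD
   12, spanning a young Medicaid-like source to an elderly Medicare-like
   source; the mean-41 database is additionally truncated at 65 years,
   emulating an employer-claims population that contains no retirees. Age
   matters for transport because the age-bin coefficients rise linearly
   with bin midpoint (0.045 log-odds per year around age 50): a model
   developed where ages above 65 are unobserved carries zero coefficients
   for the elderly bins and ranks elderly patients poorly.
2. **Case mix.** Each database shifts every feature's baseline prevalence
   on the logit scale (shifts ~ N(0, 0.4)), keeping probabilities in (0, 1)
   for any shift size. Baseline prevalences are uniform on (0.01, 0.35).
3. **Outcome rates.** Intercept shifts `delta_k` are spread evenly over
   [−0.8, 0.8]. Combined with base rates of 0.1% / 0.8% / 6% for the three
   default outcomes (rare / medium / common) and the age effects, realised
   rates span roughly 0.05% to 16% across database–outcome cells, matching
   the rare-to-common spread seen in published multi-database studies.

One database requests 25,000 patients against a 20,000-patient sampling
cap, exercising the random-subsample behaviour of very large sources.
Defaults: 5 databases × 20,000 patients, 50 condition/drug features, 20 age
bins ([0,5) … [95,∞)), one gender column.

**What the generator does not emulate.** Features are independent Bernoulli
given the profile — real comorbidities are strongly correlated. Coding
practice does not differ between databases (a condition observed in one
source would be observed in any other), so every database's model estimates
the *same* true coefficient vector and differs only through sampling noise
and unobserved strata. Passing tests therefore demonstrate the machinery
and the rate/age/label-scarcity mechanisms, not robustness to the
measurement heterogeneity of real claims-versus-EHR comparisons. A notable
structural consequence: a mid-age database with high event rates sees the
full age range with plenty of events, so its single model is nearly optimal
for the shared coefficients and can transport (in discrimination) as well
as, or marginally better than, the fused ensemble; the fusion advantage
here shows up chiefly against handicapped sources (age-truncated, young, or
event-poor) and in the spread of results, not necessarily as a uniform
median dominance over the best single database.

## Level-1 models

Per database and outcome: an 80/20 split stratified by outcome (the split
must leave ≥ 2 patients of each class), then LASSO logistic regression on
the 80%. The penalty is selected from a log-spaced grid of 25 strengths
(1e-4 … 1e2 on the inverse-prior-variance scale) by 3-fold stratified
cross-validation maximising AUROC — discrimination, not likelihood, since
ranking is what external validation measures. Ties are broken toward the
strongest penalty (sparsest model). The objective is scaled per observation
(C = 1/(λ·n)), which makes the grid meaning independent of n and guarantees
the strongest default penalty yields an intercept-only model. The intercept
is never penalised. Stratification of both the split and the folds is a
deliberate choice to keep rare outcomes estimable; it guarantees events in
every fold whenever at least 3 events exist per class.

Feature alignment at prediction time is by column name, with absent columns
contributing zero — an unobserved stratum simply carries no signal.

A *model card* packages the fitted coefficients with the internal AUROC
(computed on the 20% test split), the development-population means of the
included (nonzero-coefficient) features, the development mean age in years
and the outcome rate. The card is sufficient for every ensemble scheme; no
patient-level data crosses database boundaries.

## Metrics

* **AUROC** is rank-based (Mann–Whitney), with tied prediction pairs
  counted 0.5 — the standard convention; an exhaustive pairwise
  implementation is kept in the package purely as an independent oracle for
  the test suite.
* **Calibration-in-the-large** = observed event rate − mean predicted risk
  (positive: the model under-predicts on average).
* **Calibration gradient**: patients are sorted by prediction into up to
  100 equal-count bins (automatically reduced to n/2, minimum 2, for small
  samples) and the slope of observed event fraction on mean bin prediction
  is estimated by ordinary least squares. This binned-OLS estimator is one
  of several reasonable definitions; it is deliberately simple, and its
  sign convention makes "slope ≫ 1" mean predictions are systematically too
  small. Predictions outside [0, 1] (possible under `auc2`) are accepted by
  all metrics unchanged.

## Ensembles

* `sim` computes each member's cosine over *that member's* included
  features — the application-side mean vector is rebuilt per member. A
  degenerate (intercept-only) member has no included features, gets cosine
  0 and thereby zero weight. A shared-vector variant is not the default.
* `auc2` weights are in [−1, 1] and deliberately not normalised, and the
  combined risk is returned unclamped; the resulting calibration damage is
  part of what the evaluation is designed to expose.
* If all numerators of a normalised scheme vanish (every member at AUROC
  exactly 0.5, say), a `DegenerateWeightsError` carrying uniform fallback
  weights is raised; the experiment driver adopts the fallback and records
  a note on the affected rows.
* `ageME` gates each patient to the member minimising |dev mean age −
  patient age| (ties: lexicographically lowest database id). The absolute
  difference is used because "closest mean age" is the intended reading; a
  signed minimum would always select the youngest development population.
* Stacking draws a simple random, *unstratified* subsample of the labelled
  application data (1,000 / 10,000 / all patients), computes member risks,
  and fits an unpenalised logistic regression of the outcome on the raw
  member risks (a logit-input variant exists behind a flag, off by
  default). The Newton solver is run to tolerance 1e-10 so the MLE score
  equation holds sharply; this is what makes the all-labels stacker exactly
  calibrated-in-the-large on its fitting sample. An event-free subsample
  raises `NoEventsError` and the cell is recorded as skipped — label
  scarcity is a finding, not an error to hide.

## Leave-one-database-out protocol

One Level-1 model is trained per (database, outcome) and reused across
folds: when its database is held out it provides the internal benchmark,
otherwise it is an ensemble member. External evaluation uses the *entire*
held-out database while the internal benchmark uses only that database's
20% test split — an asymmetry kept because that is how transportability is
benchmarked in practice (the transported model faces the full population).
The stacker is fitted on a subsample of the held-out database and, by
default, evaluated on the full database including its fitting subsample
(for the all-labels stacker the fitting and evaluation sets coincide, which
is precisely why it appears recalibrated). A leakage-aware variant
(`stacking_eval_on_complement`) evaluates on the complement instead.

Any cell that cannot be computed — an untrainable member, a single-class
held-out database, an event-free stacking subsample — becomes an explicit
skip row with its reason. Every random choice (splits, folds, liblinear,
subsampling) derives its seed deterministically from the experiment seed
via CRC-32 of a purpose tag, so two runs with the same configuration are
byte-identical.

## Problem sizes and runtime

The default experiment (5 databases × 20,000 patients, 50 features, 3
outcomes) runs in ~35 s on one CPU; the homogeneous control (1 outcome)
in ~16 s; the full test suite in about a minute. These sizes were chosen so
that the rare outcome still yields 10–40 events per database — enough to
train a Level-1 model but few enough that a 1,000-patient stacking
subsample frequently contains no events at all, reproducing the
label-scarcity failure mode at desk scale.

## Known limitations

* Independence of features and shared coefficients across databases (see
  above): no measurement/coding heterogeneity, no correlated comorbidity
  structure.
* The calibration gradient estimator is a documented stand-in; other
  binning schemes or patient-level logistic recalibration slopes would give
  somewhat different values.
* No confidence intervals on AUROC, no recalibration or model-pruning
  procedures — the pipeline quantifies transport, it does not repair it.
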