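# Methods

This note documents the statistical procedures implemented in `asapval`,
the assumptions behind the synthetic-data generator, and the numerical and
design choices that were genuinely open.

## The risk model

All models are four-covariate logistic regressions on age (years), sex
(0 = male, 1 = female), and the **natural** logarithms of AFP (ng/mL) and
PIVKA-II (mAU/mL).  The natural-log convention deserves emphasis because
published formulas often write an ambiguous `log`: the coefficient and
cohort-moment magnitudes are only coherent under natural log (a mean log
PIVKA-II of 8.47 is exp(8.47) ≈ 4,770 mAU/mL, a typical HCC value; under
log10 it would be an impossible 3×10⁸).  Probabilities are clipped to
[1e−12, 1−1e−12] before any log-likelihood to avoid infinities.

## Validation metrics

* **C-statistic**: probability a random case outranks a random control,
  ties credited 0.5; computed with midranks in O(n log n), which is
  algebraically identical to exhaustive pair enumeration.
* **Calibration intercept/slope**: logistic regression of the outcome on
  the model's linear predictor — slope fixed at 1 with the LP as offset
  for the intercept-only ("in-the-large") assessment, or both free.
  (0, 1) is perfect calibration; a negative intercept means systematic
  overestimation.  Fits use IRLS (statsmodels GLM, binomial family) with
  tolerance 1e−10 and at most 100 iterations — tight tolerances matter
  because deviances feed likelihood-ratio tests.
* **Calibration curve**: loess (locally weighted linear regression,
  degree 1, default span 0.75, no robustness iterations) of outcome on
  predicted probability, evaluated at each observed prediction.  Emax and
  Eavg are the maximum and mean absolute differences between predicted and
  smoothed probabilities.  The span is a free parameter; 0.75 is the
  common default.  A delta of 0.001×range collapses near-duplicate
  abscissae so the smoother stays fast at n = 50,000.
* **Brier score**: mean squared error of the probabilities.
* **Deviance/AIC**: for Bernoulli outcomes the saturated log-likelihood is
  0, so deviance = −2·log-likelihood exactly and AIC = deviance + 2k with
  k free parameters.  A fixed published model has k = 0 (its residual df
  equals n), an intercept update k = 1, a recalibration k = 2, a revision
  k = 5.
* **Bootstrap CIs**: percentile intervals from resampling stratified by
  outcome class, 95% throughout, default 2000 replicates.  Percentile
  (not BCa) is the simplest defensible scheme when the resampling method
  is otherwise unspecified.  The point estimate always comes from the
  original sample.

## Model updating and the closed testing procedure

The three updating strategies are nested: intercept only (offset LP),
intercept + slope, full refit.  The recalibrated model's coefficients are
*exactly* slope × original coefficients (a property the tests assert at
machine precision), so discrimination is invariant across the first three
strategies.

The closed testing procedure runs likelihood-ratio tests of the revision
against, in order, the original model (df 5), recalibration-in-the-large
(df 4) and recalibration (df 3); the first non-rejection at α = 0.05 stops
the chain and that strategy is adopted, otherwise the revision is adopted.
A p-value of exactly α counts as non-significant.  This keeps the family
wise error at α while preferring the most parsimonious adequate update.

Bootstrap optimism correction (Harrell) refits the revision on each
stratified resample and evaluates it on the original cohort; the corrected
C-statistic is the apparent C minus the mean optimism, and the shrinkage
factor is the mean calibration slope of the bootstrap models on the
original data.  Default 200 replicates (a replicate count is rarely
published; 200 is the conventional minimum for stable means), minimum 50
enforced.  Separated replicates are redrawn and logged.

## Decision analysis

Positive calls use p ≥ pt (boundary inclusive); this convention makes a
"no cases below threshold" row representable when cases sit exactly at the
cutoff.  Net benefit is TP/n − (FP/n)·pt/(1−pt); decision curves compare
the model against treat-all (prevalence − (1−prevalence)·pt/(1−pt)) and
treat-none (0) over a default grid 0.01–0.99 step 0.01.

The shipped threshold menu mirrors common practice: the median non-case
prediction, the Youden-index maximizer ("optimal" cutoffs are often
reported without definition; Youden is the standard reading), the cohort
event rate, the model's published 1/3 and 2/3 decision points, 0.5, and
the median case prediction.

Risk stratification at (t_low, t_high) assigns low: p < t_low, medium:
t_low ≤ p ≤ t_high, high: p > t_high, with the medium group as the
relative-risk reference.  Relative-risk CIs use the log-normal (Katz)
method; published RR intervals computed by other variance choices can
differ slightly, so intervals are reported but no external interval is
asserted.  Two-incidence contrasts use the Pearson chi-square with Yates
continuity correction.

## Follow-up analysis

Kaplan–Meier curves (lifelines product-limit estimator; ties at a time
processed together) give per-group cumulative incidence = 1 − S(t);
groups are compared with the log-rank test implemented in-package so the
result exposes per-group observed and expected event counts (the
hypergeometric O−E machinery), with lifelines as an independent
cross-check in the test suite.  Pairwise tests are reported unadjusted.
Time starts at the first marker measurement; all censoring reasons
collapse to one censor flag.

## The synthetic cohort generator

The generator emulates a 1012-patient surveillance cohort with four
diagnostic subgroups — hepatitis (n = 451), cirrhosis (308), benign
space-occupying lesion (96), HCC (157); overall HCC prevalence 15.5% — with
per-subgroup age means/SDs, male fractions, and log-marker means/SDs.
Specifically:

* Age ~ normal truncated below at 35 (the study-inclusion age).
* Sex ~ Bernoulli(male fraction), coded 0 = male.
* (ln AFP, ln PIVKA-II) ~ bivariate normal with the configured marginals
  and a within-subgroup correlation of 0.3 — real cohorts report only
  marginals, so the correlation is an explicit assumption (configurable).
* The outcome is 1 exactly for the HCC subgroup: the generator reproduces
  a case-mix, not a data-generating logistic model.  Covariances among
  age, sex and markers beyond the marker correlation are not modelled.

Consequences worth stating: because outcomes are subgroup labels rather
than draws from any logistic model, no updating strategy is "true" on the
default cohort — the closed test may legitimately escalate to revision.
Tests that need a known truth (parameter recovery, null retention rates,
type-I error) therefore simulate outcomes from a specified model on the
generated covariates.  Passing tests demonstrate the statistical machinery
is correct, not that the generator reproduces any real cohort's joint
distribution.

Follow-up for at-risk patients uses exponential event times with
group-specific hazards.  Default hazards (5×10⁻⁴, 3.3×10⁻³,
1.4×10⁻² events/month for low/medium/high) were back-calculated once from
18-month cumulative incidences of roughly 1%, 6% and 22% via
h = −ln(1−F(18))/18 and are free parameters.  Administrative censoring is
interpreted as study-end censoring under uniform accrual — each patient's
administrative censor time is uniform on [0, horizon] with horizon
24 months — and a loss-to-follow-up fraction (default 18.8%) is censored
uniformly before that time; together these give a median observed
follow-up of about 10–11 months.  A fixed-horizon reading (everyone
censored at exactly `horizon`) cannot produce both a ~10-month median
follow-up and observable 18-month incidences, which is why the staggered
interpretation was chosen.

Determinism: one integer seed; each operation (cohort draw, follow-up,
bootstrap, optimism) derives its own deterministic sub-stream via
`default_rng([op_code, seed])`, so adding replicates to one stage never
perturbs another.

## Problem sizes used in the test suite

Moment-recovery checks use 10,000 draws (3·SE bands); parameter-recovery
and calibration-consistency checks simulate ~50,600 patients from known
coefficients; the closed-test null retention rate uses 200 simulated
cohorts of n = 1012, the LRT type-I-error check 500, and the bootstrap
coverage check 500 simulations of n = 200 with 200 inner replicates.
These sizes put Monte-Carlo noise well inside the asserted bands while
keeping the full suite around a minute of compute.

## Known limitations

* The generator's marginals-plus-one-correlation structure understates the
  dependence structure of real surveillance cohorts; etiology labels and
  longitudinal marker trajectories are not simulated.
* Only binary-outcome validation is implemented; there is no
  time-dependent C-index, Cox modelling, or competing-risks estimator.
* No penalized or Firth fitting: a separated revision raises an error
  naming the runaway direction instead of returning a boundary estimate.
* Brier scores across strategies are reported descriptively, not formally
  compared.
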