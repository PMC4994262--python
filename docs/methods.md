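# Methods

This note documents the statistical model, the synthetic-data design, the
numerical conventions, and the judgment calls made where the published
description of the original system left the design open.

## Classifier

The core model is a two-class Gaussian naïve Bayes classifier. Each
feature `j` carries four parameters — mean and standard deviation among
septic and among non-septic encounters — estimated by per-class sample
moments (SD with the n−1 denominator) over the non-missing values of that
feature only. The class prior defaults to training prevalence and can be
overridden.

**Missing data.** A feature absent from an encounter contributes to
neither class likelihood, so the posterior conditions only on what was
measured. This is the behavior that makes the model deployable on
first-hour ED data, where lab availability is strongly class-dependent
(WBC measured in ~53 % of septic vs ~22 % of non-septic encounters,
lactate in ~36 % vs ~3 %). Two consequences are worth stating plainly:

* Parameters for a sparsely measured feature are estimated from the
  *measured* subpopulation. Under class-conditional missing-at-random
  sampling (which the synthetic generator implements) this is unbiased
  within class; under severity-linked measurement in real data it is not.
* The model ignores the information in the measurement indicator itself.
  The fact that a lactate was ordered is predictive, but the published
  model does not exploit it, and neither does this one.

**Numerical conventions.** Likelihoods are accumulated in log space and
converted through the logistic function of `logit(prior) + log-LR`.
Fitted SDs are floored at `sd_floor` (default 10⁻⁶ in feature units) so a
constant column cannot create a degenerate density. Binary 0/1 columns are
accepted as "Gaussian" features if explicitly requested, but this is
discouraged and undocumented behavior beyond this note. No calibration
correction is applied to the posterior: naïve Bayes posteriors are known
to be poorly calibrated under correlated features, which is why alert
thresholds here are tuned operationally (to a sensitivity target or an
alert-burden budget) rather than interpreted as probabilities.

## Feature selection

Forward stepwise search maximizing mean bootstrap out-of-bag (OOB) AUC:
at each step every remaining candidate is added to the current set, the
model is fitted on each bootstrap resample's in-bag rows, the out-of-bag
rows are scored, and the per-replicate AUCs are averaged. The best
candidate is accepted while its gain over the current model is at least
`improvement_tol`; the baseline AUC of the empty model is 0.5.

Choices made where the original procedure is not fully specified:

* **Replicates** `n_bootstrap = 200` by default (100 in the faster test
  configurations) — enough for a stable mean at these sample sizes.
* **Stopping rule**: minimum-gain tolerance, default 0.002, plus an
  optional `max_features` cap.
* **Stratified bootstrap** by class, on by default: at a prevalence of
  0.38 % an unstratified in-bag sample would frequently contain no septic
  encounters at all.
* **Degenerate replicates** (out-of-bag set missing a class, or a feature
  with fewer than two observed in-bag values in a class) are redrawn, at
  most 10 times, rather than scored.
* **Common random numbers**: within one selection step all candidates are
  evaluated on the same bootstrap index sets, removing resampling noise
  from the between-candidate comparison.
* **Clinician preference** is formalized as a ranked list that wins ties
  among candidates whose mean OOB AUCs lie within `equivalence_band`
  (default 0.005) of the step's best — the closest testable reading of
  preferring the more easily attained of statistically equivalent
  parameters.

The published five-feature model is ambiguous about one member: one
summary lists *age*, another lists *respiratory rate*, alongside mean
blood pressure, temperature, heart rate, and WBC. Both variants are
shipped (`ABSTRACT_FEATURES`, the default, and `RESULTS_FEATURES`); no
claim is made about which the deployed system used.

## Alert evaluation

* Alerts fire at `score ≥ threshold` (ties alert).
* Candidate thresholds are the unique observed scores plus +∞; no
  interpolation. `threshold_for_sensitivity` returns the *largest*
  candidate meeting the target; `threshold_for_fp_budget` the *smallest*
  candidate within budget (maximizing sensitivity); the max-binary-AUC
  search breaks ties toward the higher threshold (fewer alerts).
* The evaluation period is 456 days (2009-04-01 through 2010-06-30
  inclusive; the 15 calendar month lengths sum to 456), which also
  reconciles the published alerts/day column with FPR × 93,421 within
  input rounding.
* Coefficients of variation use the sample SD (n−1). This convention
  reproduces the published monthly-rate CV of 16.72 % exactly.
* Report rounding follows the printed tables: percentages to one decimal,
  AUCs to three, half away from zero.
* The SIRS comparator is a configurable k-of-4 rule (abnormal temperature,
  HR > 90, RR > 20, abnormal WBC) with missing components counted as
  unsatisfied. The original "SIRS-derived" alert's published operating
  point (sensitivity 21.6 %, FPR 0.4 %) is far more specific than any
  plain ≥2-of-4 rule, so it likely carried additional conjuncts; `k` is
  left configurable and no default is claimed to match that row.

## Synthetic cohort generator

The generator exists so the pipeline can be developed and tested end to
end without protected health data. It emulates:

* **Two-class mixture.** Pooled mode draws labels Bernoulli(0.0038);
  calendar mode reproduces the study's 15 monthly encounter and sepsis
  counts exactly (93,773 and 352 in total).
* **Class-conditional marginals** calibrated to the published per-class
  medians and quartiles: location = median and scale = IQR / (2 Φ⁻¹(0.75))
  on the natural scale for normal families (temperature, pressures) and on
  the log scale for lognormal families (age, heart rate, WBC, lactate —
  the features whose printed quartiles are visibly right-skewed). A
  two-parameter family reproduces the median and the quartile spread
  exactly, but not two log-asymmetric quartiles simultaneously (e.g., the
  calibrated septic lactate q25 is 1.78 against a printed 1.9).
* **Physiological clamps** (age ≥ 14 per the inclusion criterion,
  temperature 30–43 °C, etc.) applied by clipping; a truncated-normal
  family with exact inverse-CDF sampling is also available.
* **Informative missingness**: per-class Bernoulli masks at the published
  availability rates — missing-at-random *within* class. Severity-linked
  measurement (missingness depending on anything beyond the class label)
  is deliberately out of scope.
* **Derived mean BP**: recomputed as (SBP + 2 DBP)/3 whenever both parents
  are present; drawn from its own calibrated marginal otherwise. Its
  observed-value distribution is therefore a two-component mixture, which
  the parameter-recovery tests model explicitly.
* **Concurrent screens**: the triage-nurse identification flag
  (sensitivity 54.3 %, FPR 3.1 %) and the triage screen prompt (61.9 %,
  6.8 %) as class-conditional Bernoulli indicators. The flag drives the
  comparator analytics, matching the published comparison row.
* **Respiratory rate** has no published distribution but is needed by the
  SIRS comparator and one model variant. It ships with invented, clearly
  labeled calibration: non-septic ~ N(16, 3²), septic ~ N(24, 6²),
  availability 95 % / 97 % — plausible triage values with septic
  tachypnea.
* **Dependence knob**: `class_correlation` adds equicorrelated
  Gaussian-copula dependence within class (0 = independence, the
  default). All families are monotone maps of a standard normal, so the
  copula applies uniformly.
* **Determinism**: one generator stream seeded by a single integer, drawn
  in a documented order (labels, then each feature's values and mask in
  feature order, then female / screen / flag); identical config and seed
  give a byte-identical table.

**What the generator does not emulate — and what passing tests show.**
Real first-hour data have within-class correlation (shock couples
pressure, heart rate, and lactate), severity-linked lab ordering, and
measurement artifacts; the generator matches class-conditional *marginals
only*, under independence. Under independence the naïve Bayes model is
correctly specified (up to the lognormal/Gaussian mismatch), so synthetic
discrimination is *higher* than the published real-data AUC of 0.953 and
the synthetic alert's FPR at a fixed posterior threshold is *lower* than
the published 4.7 %. The end-to-end test therefore checks a plausibility
band (continuous AUC in [0.88, 0.99] at study scale) and the operational
contract (the budget-threshold search meets ≤ 15 FP/day), not a
reproduction of the real-data point estimates. What the suite does
establish on real-data-scale inputs is the arithmetic layer: every
published quantity that is a function of other published numbers (binary
AUC identities, prevalence, CV rows, pooled sensitivity rebuilt from
monthly true positives) is reproduced to print precision.

## Test and verification design

* **Oracles**: concordance AUC is verified against both a brute-force
  pairwise count and an independent trapezoidal-ROC integration (and
  scikit-learn's implementation) to 10⁻¹²; the posterior against plain
  density-ratio arithmetic to 10⁻¹⁰; threshold searches against exhaustive
  cutpoint enumeration.
* **Calibration checks** use a balanced class mix (50,000 per class at
  n = 100,000) so per-class sampling error is negligible against the 5 %
  quantile tolerance; the 0.38 % prevalence is exercised separately where
  exact label counts are the contract.
* **Parameter recovery** fits on a 50,000-encounter balanced cohort
  generated with a normal family for every feature, so each fitted
  Gaussian parameter has an exact generator counterpart (clipped-normal
  moments in closed form; a two-component mixture for mean BP), with a
  2 % relative tolerance.
* **Selection sanity** uses one binormal feature at separation d = 2
  against the closed form Φ(d/√2) ≈ 0.921 plus two noise features, across
  20 seeded runs (n = 2,000, 100 bootstrap replicates each).

## Known limitations

* Class-conditional independence and two-parameter marginal families are
  idealizations; the generator is a test harness, not a digital twin of an
  ED population.
* The classifier discards the measurement indicator's own signal, and its
  posteriors are not calibrated probabilities.
* The original 75-variable candidate pool, the deployed SIRS-derived
  rule's exact definition, and the alert's 60- vs 90-minute scoring window
  are not publicly specified and are not reconstructed here; only
  variables with published distributions (plus the labeled respiratory
  rate) are generated.
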