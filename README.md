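# sepsiswatch

Probabilistic early identification of severe sepsis and septic shock in the
emergency department, packaged as a tested, reusable analysis pipeline.

Sepsis screening in the ED is a rare-outcome problem (roughly 4 septic
encounters per 1,000) where the clinically meaningful trade-off is not a
single accuracy number but *how many true cases an alert catches versus how
many false alarms it raises per day*. `sepsiswatch` implements the full
workflow of a deployed Bayesian sepsis alert:

* a **Gaussian naïve Bayes classifier** that handles informatively missing
  first-hour data natively — a missing lab simply drops out of the
  likelihood product, with no imputation;
* **forward stepwise feature selection** by bootstrap out-of-bag AUC, with
  clinician-preference tie-breaking between statistically equivalent
  candidates;
* **alert operating-point analytics**: sensitivity / specificity / PPV /
  NPV, false positives per day, threshold searches against a sensitivity
  target or an alert-burden budget, incremental true positives relative to
  a concurrent triage-nurse screen, and a configurable SIRS-style rule
  comparator;
* **monthly stability reporting** with min / max / coefficient-of-variation
  summaries across a 15-month calendar;
* a **synthetic ED cohort generator** calibrated to the published per-class
  medians, quartiles, and measurement-availability rates of a 93,773-encounter
  validation cohort, so the entire pipeline is testable without access to
  protected clinical data.

## The model

For an encounter with observed features `x_obs` and sepsis prior π, the
posterior is the two-class Bayes rule under class-conditional independence:

```
P(sepsis | x_obs) = π · ∏_{j∈obs} N(x_j; μ_j1, σ_j1)
                    ─────────────────────────────────────────────────────
                    π · ∏ N(x_j; μ_j1, σ_j1) + (1−π) · ∏ N(x_j; μ_j0, σ_j0)
```

where each feature carries a fitted mean and standard deviation per class
(septic = 1, non-septic = 0). Features missing from an encounter appear in
neither product, so an all-missing encounter scores exactly the prior.
Computation is in log space.

Supporting statistics follow the screening-program conventions: continuous
AUC is pairwise concordance (ties ½, equal to the trapezoidal ROC area);
a single-threshold binary alert has AUC `(sensitivity + specificity) / 2`;
alert burden is `FP count / calendar days`; stability is the sample
coefficient of variation across months.

## Worked example

```python
from sepsiswatch import *

config = default_cohort_config(calendar=True, seed=1)   # 15-month replay
cohort = simulate_cohort(config)
model = fit(cohort, cohort["sepsis"], list(ABSTRACT_FEATURES))
scores = model.score(cohort)
y = cohort["sepsis"].to_numpy()

print(len(cohort), int(y.sum()))                 # 93773 352
print(round(auc_continuous(scores, y), 3))       # 0.981

t = threshold_for_fp_budget(scores, y, 15.0, days=456.0)
rep = confusion_report(scores, y, t, days=456.0)
```

This run prints a cohort of 93,773 encounters with 352 septic (0.38 %), a
continuous AUC of 0.981, and at the 15-false-positives-per-day budget
threshold a sensitivity of 94.6 % at 15.00 FP/day (FPR 7.32 %, PPV 4.6 %).
Tuning instead for the 80 % sensitivity target gives a threshold with
80.1 % sensitivity at only 3.26 FP/day. The synthetic cohort reproduces
the study population's class-conditional marginals but not its residual
within-class dependence, so discrimination on synthetic data runs somewhat
higher than on real patients; see `docs/methods.md` for what these numbers
do and do not demonstrate.

The same pipeline is scriptable from the shell:

```bash
sepsiswatch simulate --calendar --seed 1 --out cohort.csv
sepsiswatch fit --cohort cohort.csv --out model.json
sepsiswatch evaluate --cohort cohort.csv --model model.json --days 456
sepsiswatch monthly-report --cohort cohort.csv --model model.json --out-prefix monthly
sepsiswatch audit
```

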