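# payrisk

Claims-based 30-day payment risk models for hospital condition cohorts
(acute myocardial infarction, heart failure, pneumonia): candidate-variable
construction from grouped condition categories or individual diagnosis
codes, penalized GLM selection, cross-validated model comparison, and
hierarchical-GLM hospital profiling by risk-standardized payment.

## The problem

Medicare publicly reports 30-day episode payments for AMI, HF and
pneumonia admissions, risk-adjusted so hospitals are compared on practice
patterns rather than case mix. The risk models traditionally group
ICD diagnosis codes into hierarchical condition categories (HCCs) and use a
clinically vetted algorithm to exclude index-stay diagnoses that could be
complications of care. Two coding changes make richer models possible:
present-on-admission (POA) flags distinguish pre-existing conditions from
in-hospital complications, and individual codes can replace grouped
categories as candidate variables. This package implements that model
ladder end to end and measures what each change buys.

For admission *j* at hospital *i* with positive 30-day standardized
payment *y<sub>ij</sub>* (winsorized at the 99.5th percentile):

- **Patient-level models.** GLMs `g(mu) = x'beta` with the condition's
  family/link: inverse Gaussian/log (AMI), Gamma/log (HF), Gamma/identity
  (pneumonia). `x` holds binary risk indicators under one of seven
  schemes (grouped CCs with the exclusion algorithm or the POA rule;
  index-only, pooled, or channel-separated CCs; frequency-filtered
  individual codes per channel) plus forced age bands (<=74 ref, 75-84,
  >=85). Individual-code models are selected by an L1 path (same
  family/link), capped at 200 variables, refit unpenalized, and pruned
  backward until every survivor has Wald *P* < .005.
- **Comparison metrics.** McFadden pseudo R² = 1 − ℓ₁/ℓ₀ on the full
  cohort, RMSE from 5-fold cross-validation (selection and training on
  the 80% only), and decile predictive ratios (mean predicted / mean
  actual) for calibration.
- **Hospital profiling.** A hierarchical GLM
  `g(mu_ij) = x_ij'beta + alpha_i`, `alpha_i ~ N(0, tau²)`, gives each
  hospital a risk-standardized payment
  `RSP_i = (P_i / E_i) * national mean`, with predicted `P_i` using the
  hospital's own intercept and expected `E_i` setting it to zero. Cluster
  bootstrap (resampling hospitals) yields 95% CIs; hospitals with >=25
  cases are categorized lower / no different / higher than the national
  mean, and 3×3 shift tables quantify how two models reclassify
  hospitals.

Real Medicare claims are restricted, so the package ships a synthetic
claims generator (`payrisk.simulate`) with recorded ground truth — the
test bed for parameter-recovery, calibration and ordering checks — plus
small synthetic condition-category tables in the real tables' file
format.

## Worked example

Category-shift accounting (`examples/reclassification_arithmetic.py`),
using the published AMI tallies as input:

```
              lower  no_different  higher
lower           137            24       0
no_different     90          1726      45
higher            0            73      86
hospitals: 2181
reclassified: 10.6% (share of hospitals changing category between the two models)
model B category counts: {'lower': 227, 'no_different': 1823, 'higher': 131}
pneumonia lower<->higher split forced by the accounting: 0 lower->higher, 14 higher->lower
```

Row sums are the grouped-category model's counts (161/1861/159), column
sums the individual-codes model's; 232 off-diagonal hospitals = 10.6%
reclassified, and the lower-category identity 161 − 24 + 90 = 227 checks
out. Scheme comparison on synthetic data with channel-distinct effects
(`examples/model_comparison.py`):

```
scheme           pseudo R2  CV RMSE ($)
hcc_pooled          0.0003       12,289
hcc_index           0.0015       12,096
hcc_separate        0.0017       12,115
```

Pooling index and history diagnoses into one indicator washes out their
different effects; separating the channels recovers them — the
qualitative ordering the model ladder is designed to expose. The other
examples cover simulation (`simulate_claims.py`), cohort and design
construction (`cohort_and_covariates.py`), hospital profiling
(`hospital_profiling.py`) and the one-config pipeline driver
(`full_pipeline.py`).

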