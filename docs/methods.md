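# Methods

## Scope and data model

The package models 30-day standardized episode payments for three
condition cohorts (AMI, HF, pneumonia) built from linked claims tables:
index admissions (patient, hospital, condition, age, payment, 30-day
death flag), diagnoses (per admission: code, principal/secondary role,
POA flag for index rows, index/history window), and enrollment (months of
continuous prior fee-for-service coverage). Payments are taken as already
standardized for geographic and policy variation and expressed in
constant dollars; no proration, cost-to-charge conversion or inflation
adjustment happens here. Cohort labels (which admissions are AMI/HF/PN)
are likewise inputs: reproducing the cohort ICD definitions is out of
scope.

## Cohort construction

Inclusion: cohort condition match, age >= 65 at the index admission, and
>= 12 months of prior fee-for-service enrollment (exactly 12 qualifies).
Patients who died within 30 days stay in with unprorated payments. Age
enters all models as a categorical with bands <=74 (reference), 75-84,
>=85, fixed at the index admission.

The outcome is winsorized at the 99.5th percentile, one-sided (payments
are bounded below by zero; the cap exists to limit high-cost outliers).
The quantile uses linear interpolation between order statistics — the
common statistical default, fixed and documented because the cap is
sensitive to the rule — and is computed per condition cohort after the
inclusion filters. A consequence of the interpolated cap worth noting:
re-winsorizing capped data can move values at the cap down by a hair
(the interpolated quantile of capped data sits at or below the old cap),
so winsorization is exactly idempotent only when the quantile lands on an
order statistic. Whether the original measures winsorized per condition
or pooled is not documented; per-condition is the package's choice and is
recorded in the cohort metadata.

## Covariate schemes

Comorbidity information arrives through two channels — the index claim
and all claims in the prior 12 months — and is turned into binary risk
indicators seven ways (see `payrisk.covariates`). Two rules govern which
index diagnoses count:

- **Exclusion algorithm (cms_base).** Pre-POA practice: an index
  secondary diagnosis whose condition category is on the
  potentially-a-complication list is dropped unless the same category
  also arises from the admission's history window.
- **POA rule (all other schemes).** Principal diagnoses always count; a
  secondary index diagnosis counts iff POA = "Y", or POA = "missing" and
  the code is POA-exempt (exempt codes need not be reported, so missing
  is informative there). An explicit "N" is never rescued by exemption.
  "missing" is an explicit token, distinct from the structural absence of
  POA on history rows.

Category grouping maps codes through a code->CC crosswalk and then
applies hierarchy suppression (the highest-ranked category present in a
group removes the listed lower ranks). Resolution order differs by
scheme, deliberately: `cms_base`/`cms_poa` pool the channels first and
resolve the hierarchy on the union (grouped-model practice), while
`hcc_separate` resolves per channel and `hcc_pooled` is defined as the OR
of the per-channel pair — "yes if the patient had a history or index
diagnosis or both" — which makes the pooled indicator exactly the OR of
the separated pair, an identity the tests assert. Individual-code schemes
bypass grouping entirely; a code is a candidate iff strictly more than
0.5% of cohort admissions carry it (per channel when channels are
separate; duplicates within an admission count once).

The shipped code maps (60 codes, 12 categories, 3 hierarchy groups,
5 exempt codes, 3 excludable categories) are synthetic stand-ins in the
real tables' CSV format; the algorithms, not the tables, are the content,
and users supply production tables via `CodeMaps.from_dir`.

One wording ambiguity is resolved as configuration: whether scheme (3)
split principal vs secondary *within* the index window in addition to
index vs history. Channel separation is the axis the model ladder varies,
so columns are keyed by (CC, channel) with principal/secondary retained
as provenance tags; a finer split can be expressed through those tags.

## GLMs and metrics

Family/link pairs follow the published measures: inverse Gaussian with
log link (AMI, Var = phi*mu^3), Gamma with log link (HF, Var = phi*mu^2),
Gamma with identity link (pneumonia). Fitting is IRLS on the
normal-equations with step-halving that keeps mu strictly positive and
the deviance non-increasing — the identity-link Gamma is the case that
needs it (initialized at the constant-mean solution; each Newton step is
halved until means stay positive). Convergence is relative deviance
change < 1e-12, max 200 iterations; non-convergence raises an error
carrying the iteration record. Rank-deficient designs (duplicated
indicator columns) fail fast in the Gram factorization. The in-house
fitter is cross-checked against statsmodels on Gamma/log fixtures in the
test suite (coefficients to 1e-6, standard errors to 1e-4).

Dispersion phi is the Pearson chi-square estimate at the final fit (the
measures do not state their estimator; Pearson is the profiling-world
default). McFadden pseudo R² = 1 − ℓ₁/ℓ₀ evaluates both log-likelihoods
at the full model's phi, so the ratio reflects mean-structure improvement
only; it is clipped to [0, 1] for reporting, and the intercept-only model
scores exactly 0 because every family/link pair here solves sum(y − mu) = 0
at mu = y-bar. Note that the *ratio* is not invariant to rescaling the
outcome (both log-likelihoods shift by −n·ln c under y → c·y); the
likelihood-ratio difference is, and that is the invariance the property
tests pin down. RMSE is the plain root mean squared prediction error in
dollars.

### Penalized selection

For individual-code models: an L1 path for the matched family/link,
computed by cyclic coordinate descent on the IRLS working response over a
100-point log-spaced penalty grid (lambda_max down to 1e-3·lambda_max)
with warm starts. Candidate columns are standardized internally;
intercept and age bands are never penalized. The descent runs on the Gram
matrix of the standardized design with an active-set strategy (KKT checks
pull in violators), so a coordinate update is O(p); for Gamma/log the
IRLS weights are identically 1 and one Gram serves the whole path. The
smallest penalty whose active set holds <= 200 variables is chosen, the
set is refit as an ordinary GLM, and backward elimination repeatedly
drops the least significant variable with two-sided Wald P >= .005 and
refits — single-pass screening can leave insignificant survivors after
refitting, backward elimination cannot. The path metadata and pruning log
account for every variable considered and dropped.

### Cross-validation

5 folds by admission (patient-level grouping is available but not the
default; the models are admission-level). Per fold, selection (code
schemes only — grouped schemes fit all their columns) and training use
the 4/5 training split; RMSE is computed on the held-out fifth. The
full-cohort pseudo R² comes from a separate selection-plus-fit on all
admissions, matching how the comparison table pairs an in-sample
discrimination measure with an out-of-sample error. The candidate
frequency filter is part of design construction and computed once on the
cohort.

## Hospital profiling

Random-intercept GLM on the link scale, alpha_i ~ N(0, tau²). Estimation
alternates: (1) IRLS update of beta given alpha; (2) closed-form raw
per-hospital intercepts of the working residual, a method-of-moments
update tau² = max(0, var(a_i) − mean(phi / sum_i w)) and ridge shrinkage
alpha_i = a_i·tau²/(tau² + v_i). This penalized-quasi-likelihood-style
estimator is standard for profiling models; a full integrated likelihood
is out of scope, and the estimator is validated by parameter recovery
(tau = 0.2 recovered within [0.15, 0.25] with rank correlation of
alpha-hat vs truth above 0.9 at 100 hospitals × 200 cases).

RSP_i = (P_i / E_i) × national mean, where P sums g⁻¹(x'beta + alpha_i)
over the hospital's cases and E sets alpha to its prior mean 0
("expected" = an average hospital with this case mix; configurable to
mean(alpha-hat)). Under a log link P/E = exp(alpha_i) exactly, a case-mix
invariance the tests assert. The national mean is the observed mean
winsorized payment over the whole condition cohort, including admissions
at below-threshold hospitals (winsorized, for internal consistency with
the modeled outcome).

Confidence intervals: cluster bootstrap resampling hospitals with
replacement — the target of inference is the hospital effect — refitting
the hierarchical model and recomputing the national mean per replicate,
each original hospital collecting the RSP of every copy of itself;
percentile 2.5/97.5 bounds (no BCa, for determinism and simplicity).
Hospitals never sampled across replicates get undefined CIs and are
excluded from categorization. The production default is 2000 replicates;
tests and the bundled examples run 200 to keep runtimes in seconds, which
widens nothing conceptually (percentile endpoints are just noisier).
Categorization applies to hospitals with >= 25 cases: CI entirely above
the national mean -> higher, entirely below -> lower, else no different.

Shift tables cross-classify hospitals by category under two models;
percent reclassified is the off-diagonal share. The accounting identities
(column sums = model-B counts = model-A counts plus net shifts) are exact
and let printed marginal counts pin down unprinted cells — including the
direction of lower<->higher jumps.

## The synthetic generator

`payrisk.simulate` emulates the structure the estimators assume: one
index admission per patient; ages mostly 65+ (a small configurable
under-65 tail exercises the exclusion); hospital case volumes from a
mixture placing ~20% of hospitals under the 25-case threshold (no volume
distribution is documented for the real cohorts; this choice exercises
the eligibility filter); per-code arrival probabilities per channel
spanning the 0.5% frequency filter; POA flags per code over
{Y, N, missing}; payments drawn from the condition's family/link around
g⁻¹(x'beta + alpha_hospital) with the generator parameterized exactly as
the estimator's variance function (Gamma Var = phi*mu², inverse Gaussian
Var = phi*mu³ via the Wald sampler); death as an independent Bernoulli
flag that does not alter payment (decedent payments are not prorated);
and an exact-count fraction of patients with < 12 enrollment months.
Default intercepts and dispersions put mean payments near the observed
national means (~$23k AMI, ~$16k HF, ~$17k PN) with matching coefficients
of variation; dispersion is the only tail knob, as nothing is documented
about the pre-winsorization tail beyond its existence. Identity-link
configurations whose realized linear predictor is non-positive are
rejected with a diagnostic. One PRNG substream per table, all derived
from the single seed, so extending one table never perturbs another.

What the generator does not emulate — and hence what green tests do not
establish about real claims: multiple admissions per patient, coding
intensity that varies by hospital, payment standardization itself,
transfer logic, correlated code co-occurrence, or a heavier-than-Gamma
payment tail. Recovery and calibration results here certify the
estimators under their assumed model, not the assumptions.

## Numerical and design choices

- Quantile/decile bins: stable argsort with near-equal splits (sizes
  differ by at most one); ties broken by input order — payments rarely
  tie, synthetic data can.
- Decile predictive ratios satisfy an exact identity: weighting each
  bin's ratio by its actual total recovers overall mean(pred)/mean(actual).
- Bootstrap replicates that fail to converge (degenerate resamples) are
  discarded rather than propagated; they are rare and logged by count in
  the draw totals.
- All pipeline randomness flows from one config seed through named,
  crc32-keyed substreams (simulation, CV folds per condition/scheme,
  bootstrap per condition/scheme), so runs are reproducible and stages
  independent.
- Problem sizes used by the test suite and the acceptance script
  (n = 20 000 for recovery and calibration, 100 × 200 for hierarchical
  recovery, n = 50 000 × 300 candidates for selection, 100 × 40 with 200
  bootstrap replicates for the null categorization rate) are the
  package's chosen desk-scale study conditions; they are stated here once
  and not tuned per test.

## Known limitations

- The hierarchical estimator is PQL-style; for very small hospitals or
  tau near zero its tau-hat is truncated at 0 rather than profiled.
- Selection inference is not adjusted for the selection step (the
  original pipeline did not adjust either); reported P-values are
  conditional on the chosen set.
- The L1 path uses the matched family/link; a Gaussian working-response
  variant is not currently exposed.
- Winsorization interacts with calibration at the top decile: a
  correctly specified model predicts uncapped means, so top-decile
  predictive ratios sit slightly above 1 at aggressive caps.
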