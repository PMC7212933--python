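# Methods

## The model under validation

PICNICC is a logistic regression predicting microbiologically documented
infection (MDI) in a paediatric febrile-neutropenia episode. Its linear
predictor is

LP = α + β_tumour(type) + 0.57·(T − 37) + 0.79·unwell + 0.18·Hb
   − 0.30·ln(WCC) − 0.21·ln(AMC)

with tumour-type log odds ratios against an acute-lymphoblastic-leukaemia
reference, ranging from +0.92 (high-risk neuroblastoma) to −14.16
(low-grade brain tumour; an artefact of complete separation in the
derivation data, preserved as published because it is what a user of the
published model would compute). The published reports never print the
intercept α. `ModelSpec` therefore requires it explicitly; the packaged
default uses a placeholder of −4.27, calibrated once so that the mean
predicted risk over the default synthetic population is ≈ 0.25 (matching
the conventional figure that roughly a quarter of febrile-neutropenia
episodes have a documented infection). Every load of the default spec logs
that the intercept is not a published value.

Units are fixed: temperature in °C, haemoglobin in g/dL (the loader
rejects a declared mmol/L and performs no conversion), counts in 10⁹/L.
WCC or AMC of exactly zero would make the log undefined; the scorer
substitutes 0.005 ×10⁹/L (half a typical assay floor, configurable) and
warns, preserving complete cases without inventing a clinical rule.

## Per-study validation

All metrics are computed on complete cases (every covariate and the
outcome present); dropped counts are logged per field and an empty study is
excluded with a reason rather than aborting the run.

* **C-statistic**: Mann–Whitney concordance via midranks, ties counted ½ —
  stated explicitly because rank-based shortcuts differ on ties.
* **E/O ratio**: Σ predicted risk / Σ observed events; undefined with zero
  events (study excluded from E/O pooling, logged).
* **Calibration slope and intercept**: ML logistic refit
  logit P(y=1) = a + b·LP (statsmodels GLM/Binomial, tol 1e-10); model-based
  SEs. Separately, a calibration-in-the-large intercept is fitted with the
  LP as a fixed offset (slope held at 1); the joint-fit intercept and the
  offset-fit intercept answer different questions, so both are reported —
  the offset fit drives the intercept-update recalibrations.
* **Confusion at the threshold**: an episode is low-risk iff predicted risk
  ≤ 0.10 (boundary inclusive); a high-risk call on an event is a true
  positive.
* **Calibration plot data**: equal-count (quantile) bins of predicted risk;
  heavy ties collapse bins, logged.

Uncertainty comes from a nonparametric bootstrap over episodes (default
2000 draws), taken on the pooling scale: SD of logit(C) and of ln(E/O)
across resamples, with percentile 95 % intervals. Draws on which a metric
is undefined are dropped and counted; >50 % undefined flags the SE
unstable. A closed-form alternative (`se_method="analytic"`: Hanley–McNeil
for C, delta method for ln E/O) exists for large simulation studies where
thousands of bootstraps would dominate runtime; the Hanley–McNeil form also
serves as an independent oracle for the bootstrap in the tests. Slope and
intercept SEs are always the model-based ones.

## Pooling

Random-effects meta-analysis with inverse-variance weights
w_i = 1/(v_i + τ²), pooled SE = (Σw_i)^(−1/2), normal 95 % CI, and the
Higgins–Thompson–Spiegelhalter 95 % prediction interval
pooled ± t_{k−2,0.975}·√(τ² + SE²) (reported only for k ≥ 3). τ² is the
REML estimate, computed by the standard estimating-equation iteration
(tolerance 1e-8, max 100 iterations, floored at 0) with a
DerSimonian–Laird fallback on non-convergence (logged). Analysis scales —
logit for C, log for E/O, identity for slope and intercept — are this
package's choice (standard for keeping estimates in range; the sources on
which the method is based do not state scales); everything is
back-transformed for reporting.

Meta-regression (used by recalibration strategy C) fits
y_i = a + b·x_i + u_i + e_i with residual τ² estimated by bounded
maximisation of the profiled restricted likelihood
(`scipy.optimize.minimize_scalar`, xatol 1e-10, τ² = 0 checked explicitly).
The scalar profile optimiser is used here instead of the pooling module's
fixed-point iteration because the regression-REML estimating equation is
less robust with k as small as 3 and a near-collinear design; the two
agree on pure pooling problems.

Sensitivity and specificity at the threshold are pooled jointly: per-study
logit Sn and logit Sp with approximate binomial within-study variances
(1/x + 1/(n−x); +0.5 continuity correction on any zero cell, logged), a
2×2 between-study covariance Ψ parameterised as (log sd, log sd, atanh ρ)
and estimated by REML (Nelder–Mead on the restricted likelihood), GLS for
the pooled means — a Reitsma-style linear mixed model rather than the
exact binomial likelihood, chosen for stability at these study counts. On
optimiser failure the two traits are pooled independently and the
correlation reported as unavailable. Confidence (and prediction) ellipses
for ROC space derive from the sampling covariance of the pooled point
(plus Ψ).

## Recalibration strategies

A. Global intercept = REML-pooled mean of derivation study-level
   intercepts. These are not publicly available, so they are accepted as
   configuration; a single supplied value is used directly with a warning.
B. Per-study intercept α\* solving mean_i expit(α\* + LP0_i) = observed MDI
   proportion by bracketed Brent root finding (xtol 1e-10; the mean risk is
   strictly increasing in α\*, so the root is unique). By construction the
   study's E/O becomes exactly 1. The cruder logit(rate) − mean(LP0)
   shortcut is kept as an option and test comparator.
C. The per-study offset-fit intercept updates are regressed on MDI
   proportion by random-effects meta-regression; each study receives the
   fitted value at its own proportion (extrapolation warns; a constant
   covariate degenerates to pooled-mean intercepts, flagged). Where the
   intercept–rate relation is close to linear, B and C give nearly
   identical intercepts.
D. Per-study betas multiplied by the study's joint-fit calibration slope
   b_s; the intercept appropriate to the rescaled betas, a_s + b_s·α₀, is
   REML-pooled across studies (unweighted mean behind a flag — the sources
   do not state which average) and shared. Because the new LP is an affine
   transform of the old one with scale b_s, the refitted calibration slope
   is exactly 1 per study, and the C-statistic is unchanged whenever
   b_s > 0; a negative b_s inverts the ranking and triggers a warning.

Strategies A–C never touch the betas (asserted bitwise in the tests).
Intercept-only updates can fix calibration-in-the-large but cannot move the
refitted slope, which stays near the generator's shrinkage factor — the
structural reason simple recalibration cannot rescue a model whose
predictor effects do not transfer.

The exploratory coefficient refit stacks all complete cases and fits the
full covariate set by ML logistic regression. Empty tumour categories are
reported as absent; separated categories (tiny groups with uniform
outcomes) are reported exactly as the fit returns them — extreme estimate,
enormous SE — because that is the honest summary of such cells.

## Synthetic cohorts

Outcomes are drawn as Bernoulli(expit(δ_s + λ·LP)) where LP is the scoring
model's own linear predictor. λ (default 0.03) shrinks the predictor
effects — the default emulates the near-flat calibration slope the model
showed on real validation cohorts — and δ_s is tuned per study by Brent
root finding so the expected MDI rate hits its target (defaults: the seven
published cohort rates 19/21/31/26/19/18/24 %). Setting targets to None
with δ = 0, λ = 1 gives the correct-specification mode in which outcomes
come from the model's own risks, the anchor for the E/O = 1 and slope = 1
limits.

Study sizes default to the published 48/47/167/121/27/101/648 (total
1159). The tumour mix is proportional to the published pooled per-category
episode tallies (reference category 556/1152 ≈ 48 %). Covariate
distributions are invented but clinically plausible, and config-exposed:
temperature truncated-normal 38.4 ± 0.6 °C on [38, 41]; 10 % severely
unwell; haemoglobin normal 9.5 ± 1.8 g/dL truncated positive; WCC and AMC
log-normal with medians 1.2 and 0.1 ×10⁹/L (σ = 0.8, 1.0). Episode
clustering within patients (geometric, mean 2 episodes/patient) is
generated via patient ids but ignored by the episode-level analysis,
matching the complete-case design; covariates are drawn independently of
one another.

What the generator does **not** emulate: the real cohorts' joint covariate
correlations, their between-study case-mix differences (all synthetic
studies share one covariate distribution, so between-study heterogeneity
in C and slope is purely sampling noise plus the rate targets), and the
systematic case-mix shift that produced the large real-data
overestimation of risk. Consequently a passing pipeline here demonstrates
the estimators and identities are correct, not that any real cohort would
show these values. Under the default conditions the mean predicted risk
(0.25 by the intercept calibration) sits only slightly above the weighted
observed rate (0.2425), so the default pooled E/O is only mildly above 1;
the overestimation property is therefore tested as a mean across 200
Monte-Carlo replicates of the full seven-study design, where it is clearly
significant, rather than within a single replicate.

## Numerical choices and degenerate inputs

* Fixed seeds everywhere: one root `SeedSequence` spawns independent child
  seeds per study (generation and bootstrap), so any study is reproducible
  in isolation and results are bit-identical under a repeated seed.
* Metrics with unmet preconditions (single-class outcomes, zero events,
  constant LP) raise a typed `MetricUndefinedError`, which the study-level
  driver converts to flags and the pooling layer to exclusions — a run
  never aborts on a degenerate study; only "no usable studies" is fatal.
* The low-risk boundary is inclusive (risk exactly 0.10 is low-risk).
* No multiplicity adjustment is applied anywhere: each metric is reported
  with its own CI, and the package makes no joint claims across metrics.
* Problem sizes in the test suite (20 000-episode self-consistency cohorts,
  50 000-episode correct-specification limit, 200-replicate recovery study
  at the published cohort sizes) were chosen as the smallest at which the
  Monte-Carlo tolerances asserted are comfortably valid for the
  approximations involved; the smallest published cohorts (27–48 episodes)
  are themselves near the floor at which logistic refits behave, which is
  why the recovery study does not shrink them further.

## Known limitations

* The placeholder intercept makes absolute risk levels conventional, not
  published; any conclusion that depends on α should treat it as a free
  configuration.
* The bivariate model uses normal within-study approximations; with very
  small cells its CIs can differ from exact-binomial implementations.
* The bootstrap treats episodes as independent, ignoring the within-patient
  clustering the generator creates (the analysis is episode-level by
  design); a patient-level bootstrap is a natural extension and is not
  implemented.
* Meta-regression on 7 studies with 1 covariate has 5 residual degrees of
  freedom; its interpolations are smoothing devices, not strong inferences.
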