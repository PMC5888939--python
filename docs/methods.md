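# Methods

## Target parameter and identification

The estimand is the average treatment effect on the risk-difference
scale, `psi = E[Y(1)] − E[Y(0)]`, for a binary exposure `A` and a
binary one-year mortality indicator `Y`.  Identification rests on the
usual assumptions: conditional exchangeability given the confounder
set `W = (W1, W2, W3, W4)` (socioeconomic status, age, cancer stage,
comorbidity), positivity (`0 < g(W) < 1` with
`g(W) = P(A=1 | W)`), and consistency.  All estimators standardize
over the empirical covariate distribution, so `psi` is the sample-
averaged risk difference.

## Estimators

**Naive regression adjustment.** A linear-probability OLS regression
of `Y` on `A` and main-effect covariate terms; `psi` is the
coefficient on `A`, with an HC1 heteroskedasticity-robust SE.  This is
deliberately the field's "conventional adjustment": under effect
heterogeneity it estimates a conditional-variance-weighted average of
stratum effects, not the ATE, and is the benchmark's negative control.
(A correctly specified g-computation would be unbiased and would make
a poor negative control; the coefficient form reproduces the
characteristic over-/under-adjustment failures.)

**IPTW-RA.** The propensity model is fitted by maximum likelihood;
subjects are weighted by `1/g` (treated) or `1/(1−g)` (controls;
unnormalized Horvitz–Thompson weights by default, stabilized weights
behind a flag).  Weighted *logistic* outcome regressions are fitted
separately per arm — logistic rather than linear so that predictions
stay in `[0, 1]` — and `psi` is the mean difference of the two arm
predictions over all subjects.  The SE comes from the stacked
M-estimation sandwich over four sets of estimating equations
(propensity score, both weighted outcome fits, and the
standardization equation), so propensity and outcome estimation are
propagated; a fixed-weight variant is available.

**AIPTW.** The one-step efficient estimating equation
`psi = mean[q1 − q0 + A(Y−q1)/g − (1−A)(Y−q0)/(1−g)]` with the
outcome model fitted as a single logistic regression in `A` and the
covariate terms.  SE = sample SD of the summand over `sqrt(n)`.  The
raw `1/g` terms are used as-is; fitted propensities outside
`(ps_tol, 1−ps_tol)` raise a positivity error (default tolerance
1e-5, relaxed to 1e-8 in the adaptive benchmark), mirroring the
weight-tolerance behavior of standard implementations.  The point
estimate may leave `[−1, 1]` under extreme weights — this is a
documented property, not a bug, and one of the benchmark's findings.

**TMLE.** Initial `g` and `Q` come from the super learner by default
(or from parametric specifications, or injected values).  `g` is
bounded to `[0.025, 0.975]`, `Q` truncated to `[1e-6, 1−1e-6]` before
logit transforms.  The fluctuation step is an intercept-free logistic
regression of `Y` on the two clever covariates `h1 = A/g` and
`h0 = −(1−A)/(1−g)` with offset `logit(Q(A,W))`, solved by Newton
iteration (max 50 iterations, tolerance 1e-10; the two covariates
have disjoint support so the problem separates).  Updated predictions
`q1* = expit(logit(q1) + eps1/g)`, `q0* = expit(logit(q0) −
eps0/(1−g))` give the substitution estimate `psi = mean(q1* − q0*)`,
which cannot leave `[−1, 1]`.  The SE is the sample SD of the
efficient influence curve over `sqrt(n)`; after convergence the
empirical mean of the influence curve is zero to machine precision
(asserted to 1e-8 in the tests).  A single-epsilon fluctuation
variant is available behind a switch.

All confidence intervals use the normal multiplier 1.96.

## Nuisance estimation

Logistic fitting is a Newton/IRLS maximum-likelihood core with
step-halving, least-squares steps on singular information matrices,
and a rank-aware parameter count: exactly collinear designs (for
example the square of a binary covariate in the candidate ladder) are
detected up front, fitted on a pivoted independent column subset, and
reported with zero coefficients on the dropped columns and `k = rank`
in AIC/BIC.  Convergence uses tolerance 1e-8 on the coefficient step
with a 100-iteration cap; separation is reported through a warning
and a `converged=False` flag, never a silent failure.  This core was
written in-house because the Monte Carlo benchmark performs on the
order of 10^5 small logistic fits per run; it is cross-checked against
statsmodels GLM (coefficients, log-likelihood, AIC, weighted fits) in
the test suite.

**Best-fit selection.** Candidates grow in a fixed nested order —
each main effect, then each squared term, then each pairwise product
— ending at the fully interacted order-2 polynomial (14 non-intercept
terms for four covariates).  Every candidate is fitted; ranking is by
AIC (default) or BIC, ties broken toward fewer parameters, then
earlier enumeration.  Disagreement between the two criteria is
visible in the returned table.

**Super learner.** V-fold cross-validation (default 10 folds, 5 in
the scaled profile), stratified on the response so that rare classes
reach every training fold (switchable to plain random folds).  The
library is (1) bidirectional stepwise-AIC logistic selection over
main terms plus all pairwise products, (2) a main-terms GLM, (3) a
GLM with squares of non-binary terms and all pairwise products.
Ensemble weights minimize the level-one squared error by non-negative
least squares, renormalized to the simplex (log-loss behind a
switch); an all-zero solution falls back to the minimum-CV-risk
learner.  Predictions are truncated to `[1e-6, 1−1e-6]`.

The stepwise learner screens candidate moves cheaply — additions by
the Rao score statistic, deletions by the Wald statistic, both
computed from the current fit in O(nk) per candidate — and then
verifies the best screened move with an exact refit, accepting it
only if the exact AIC improves (the runner-up is tried once before
stopping).  The scan order is deterministic, so the selected model is
reproducible; the screened search visits a subset of the moves a
full-refit stepwise would score, which is the price of running inside
a cross-validated ensemble at n = 10,000.

## Synthetic cohorts

Covariates emulate the registry setting: `w1` ~ discrete uniform
{1..5} (deprivation quintile), `w2` ~ uniform(0,1) (age score),
`w3` ~ discrete uniform {1..4} (stage), `w4` ~ Bernoulli(0.5)
(comorbidity).  Exposure follows a logistic model in `W`; the outcome
a logistic model in `(A, W)` that always includes the `w2·w4`
product.  One global seed expands into independent substreams for
covariates, treatment and outcome, so each stage is separately
reproducible.  Near-positivity is induced by scaling the treatment
model's covariate coefficients (the `positivity_severity` knob), never
by discarding samples; severity 0 collapses the propensity to a
constant, and the lower percentile decreases monotonically as the
knob grows.

Two calibrated configurations ship with the package (see
`scripts/calibrate_dgp.py` for the procedure; shape coefficients were
fixed first, then the treatment coefficient of each outcome model was
solved by root-finding on the plug-in truth and frozen):

* **Scenario 1** (correct-specification benchmark): true ATE
  −0.1813; main-terms treatment model with a lower propensity tail
  around 0.02–0.03; moderate outcome interaction.  A main-terms
  linear regression overestimates the effect magnitude by roughly a
  fifth and its CIs undercover (~85%), while correctly specified
  double-robust estimators are unbiased with ~94–95% coverage.  The
  tail depth was chosen jointly with the naive bias: a substantially
  deeper tail makes influence-curve SEs understate the sampling
  spread at n=1,000 and drags double-robust coverage toward 91%.
* **Scenario 2** (dual-misspecification benchmark): true ATE
  −0.1172; both generating models carry linear *and curved*
  age-by-comorbidity terms (`w2:w4`, `w2^2:w4`).  The curved term
  lies outside the span of any order-2 polynomial, so the best-fit
  ladder and the order-2 super-learner library remain slightly
  misspecified even after selection — which is what the benchmark is
  about.  The propensity profile among comorbid older patients dips
  to ~0.01 and flattens; order-2 propensity fits extrapolate past the
  flattening and systematically understate `g` there, so raw
  inverse-probability weights become erratic.  This reproduces the
  characteristic instability of AIPTW (spread roughly double that of
  TMLE and IPTW-RA, heavy-tailed replication means) while the
  bounded, substitution-based TMLE stays accurate; a main-terms
  linear regression attenuates the effect by roughly 90%.

The true ATE of either configuration is computed by plug-in: average
`Q0(1,W) − Q0(0,W)` over 10^6 fresh covariate draws (no outcome
sampling), giving a covariate-only Monte Carlo error near 4e-4.

**Lung-cancer cohort emulator.** 183,426 patients (102,535 men,
80,891 women); age normal per sex (means 72.6/73.0, SDs 10.3/10.8);
emergency presentation Bernoulli(0.35) and stage distribution
(0.15, 0.10, 0.25, 0.50) — both chosen as realistic for English lung
cancer since the source margins are not published at that
granularity; deprivation quintile and comorbidity quartile uniform.
One-year death is drawn from the published conditional mortality
table by sex and emergency status (default) or by sex and stage
(switch).  The emulator reproduces those conditional margins only —
the joint law of exposure, stage and death is deliberately not
modeled, so the cohort is a calibration target and illustration, not
a re-creation of the registry.  Passing tests on it show the margins
are matched, nothing more.

## Monte Carlo harness

Per-replication seeds derive deterministically from (master seed,
replication index), so any replication can be re-run in isolation.
Estimator failures (positivity errors, non-convergence) are recorded
per replication and excluded from the metrics with their count
reported; an estimator failing in more than 20% of replications is
flagged unreliable.  Metrics per estimator: mean estimate, SD across
replications, `abs_bias = |mean − psi0|`,
`rel_bias = 100·abs_bias/|psi0|`, `rmse = sqrt(mean((psi_r −
psi0)^2))`, and 95% CI coverage of `psi0` using each replication's
own influence-curve CI.  The identity `rmse² = bias² +
sd²·(reps−1)/reps` holds exactly and is asserted in the tests.

The full-fidelity profile follows the benchmark design (1,000
replications; 10 super-learner folds).  The scaled profile used by
the acceptance checks runs 200 replications at n=10,000 with 5 folds,
and 400 replications for scenario-1 TMLE coverage at n=1,000 — sizes
chosen so a complete acceptance run stays within a desk-scale
single-core session.  At 200 replications the Monte Carlo SE of a
relative-bias estimate is about 1% for the stable estimators and
larger for AIPTW (whose replication distribution is heavy-tailed
under scenario 2), so small bias differences between TMLE and
IPTW-RA are not resolvable at this scale; the acceptance checks
therefore assert the stable signatures (AIPTW's inflated SD and
worst RMSE, TMLE's smallest RMSE and near-zero bias) rather than a
three-way ordering of near-zero biases.

## Numerical choices

* Probabilities are clipped to `[1e-6, 1−1e-6]` before any logit.
* Propensity bounding `[0.025, 0.975]` applies inside TMLE only;
  IPTW-RA and AIPTW use the raw fitted propensities with a weight
  tolerance (`ps_tol`) below which estimation refuses.
* The fluctuation and all logistic fits are exact Newton solves with
  step-halving; no stochastic optimization anywhere, so every
  estimate is reproducible bit-for-bit given seeds.
* Ties in model selection break toward smaller models, then earlier
  enumeration order.
* Empty treatment arms raise estimation errors; an empty arm in the
  overlap summary is flagged, not fatal.

## Limitations

* The synthetic generating processes are calibrated reconstructions:
  they reproduce the published truths, bias magnitudes and
  qualitative estimator behavior, but they are not the original
  (unpublished) coefficient sets, and conclusions about exact bias
  percentages transfer only approximately.
* The learner library is deliberately small (stepwise, GLM, order-2
  GLM); richer libraries (splines, boosting, random forests) would
  change the scenario-2 numbers and are out of scope here, though the
  learner interface accepts any object with `fit`/`predict`.
* Binary outcomes and point exposures only; no censoring,
  time-to-event structure, or survey weights.
* The naive estimator's exact form in the comparison literature is
  underdetermined ("multivariate regression adjustment"); the
  linear-probability coefficient was chosen as the form whose failure
  modes match the reported behavior, and the choice is isolated in
  `naive_ate`.
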