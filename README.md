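# drate — double-robust risk-difference estimation for binary exposures

`drate` implements and benchmarks estimators of the **average treatment
effect (ATE)** on the risk-difference scale,

```
psi = E[Y(1)] - E[Y(0)],
```

for a binary exposure `A` and a binary outcome `Y` (here: death within
one year of a cancer diagnosis), adjusting for a confounder set
`W = (W1, W2, W3, W4)` — socioeconomic status, age, cancer stage and
comorbidity.  It is aimed at epidemiologists and biostatisticians who
want to understand how these estimators behave under the two failure
modes that dominate population-based registry analyses: **model
misspecification** and **near-positivity violations** (propensity
scores `g(W) = P(A=1 | W)` close to zero).

Four estimators are provided, each with influence-curve-based
standard errors and 95% confidence intervals:

| estimator | idea | failure mode probed |
|---|---|---|
| `naive_ate` | linear-probability regression of `Y` on `A, W`; the coefficient on `A` | biased for the ATE under effect heterogeneity |
| `iptw_ra_ate` | inverse-probability-weighted per-arm outcome regressions, standardized over the sample | extreme weights inflate variance |
| `aiptw_ate` | augmented IPTW: `mean[q1 - q0 + A(Y-q1)/g - (1-A)(Y-q0)/(1-g)]` | raw `1/g` terms can leave `[-1, 1]` |
| `tmle_ate` | targeted maximum likelihood: logistic fluctuation of an initial outcome fit along the clever covariates `A/g`, `-(1-A)/(1-g)`, then plug-in | substitution estimator, respects `[-1, 1]`; propensity bounded to `[0.025, 0.975]` |

Nuisance functions come either from parametric logistic specifications
(a small term language: `"w1"`, `"w2:w4"`, `"w2^2"`), from AIC/BIC
**best-fit selection** over a nested candidate ladder up to a fully
interacted order-2 polynomial (`enumerate_candidates` /
`bfit_select`), or from a V-fold cross-validated **super learner**
over three learners (stepwise-AIC selection, main-terms GLM, order-2
interaction GLM) with non-negative-least-squares ensemble weights.

A synthetic-cohort module ships two calibrated generating processes
(true ATEs −0.1813 and −0.1172) with a severity knob for
near-positivity, plus an emulator of a 183,426-patient lung-cancer
cohort calibrated to published one-year mortality margins by sex and
emergency-presentation status.  A Monte Carlo harness turns any
configuration into the standard benchmarking table: mean estimate
(SD), absolute/relative bias, RMSE, CI coverage.

## Worked example

```python
from drate import (ModelSpec, aiptw_ate, generate_scenario_dataset,
                   iptw_ra_ate, naive_ate, scenario1, tmle_ate)

cohort = generate_scenario_dataset(scenario1(), n=5000, seed=11)
tspec = ModelSpec("treatment", ("w1", "w2", "w3", "w4"))
ospec = ModelSpec("outcome", ("w1", "w2", "w3", "w4", "w2:w4"))

print(naive_ate(cohort).psi)
print(iptw_ra_ate(cohort, tspec, ospec).psi)
print(aiptw_ate(cohort, tspec, ospec).psi)
print(tmle_ate(cohort[["w1","w2","w3","w4","a","y"]], v=5, seed=1)[0].psi)
```

prints (true value −0.1813):

```
-0.23332941281946984
-0.18401594984646202
-0.18311400622745008
-0.18380065235829565
```

The naive coefficient overstates the protective effect by about a
fifth because it averages heterogeneous stratum effects with
variance-based weights; the three double-robust estimators agree with
each other and sit within one standard error of the truth.  The
`examples/` directory holds one short script per capability
(simulation and overlap diagnostics, estimation, best-fit selection,
super learner, Monte Carlo, lung cohort); each prints a small table
and a line on how to read it.

A thin CLI mirrors the library for shell use:

```bash
drate generate --scenario 1 --n 1000 --seed 3 --out cohort.csv
drate estimate --input cohort.csv --method tmle --seed 3
drate bfit     --input cohort.csv --response y --criterion aic
drate simulate --scenario 2 --n 10000 --profile scaled --seed 5 --out-dir results/
```

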