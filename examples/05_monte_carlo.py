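"""A small Monte Carlo benchmark of the four estimators.

Fifty scenario-1 replications at n=1,000 (a desk-scale sketch of the
full 1,000-replication benchmark).  The summary mirrors the standard
benchmarking table: mean estimate (SD), absolute and relative bias,
RMSE and 95% CI coverage against the known truth.
"""

from drate import MCConfig, default_estimators, report_table, run_monte_carlo, scenario1
from drate.datagen import TRUE_ATE

config = MCConfig(
    dgp=scenario1(),
    n_per_rep=1000,
    reps=50,
    estimators=default_estimators(profile="scaled"),
    master_seed=7,
)
summary = run_monte_carlo(config, true_ate=TRUE_ATE[1])
print(f"true ATE: {summary.true_ate:+.4f}\n")
print(report_table(summary).to_string(index=False))
print("\nExpected pattern: the naive row overstates the effect and "
      "undercovers; the double-robust rows are nearly unbiased with "
      "coverage near 95%.")
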