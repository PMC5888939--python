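"""Simulate a benchmark cohort and inspect propensity-score overlap.

Draws one scenario-1 cohort (four confounders, binary exposure,
binary one-year death) and prints the true propensity distribution at
two severity settings.  The severity knob scales the treatment-model
coefficients: larger values push the lower tail of g0(W) toward zero
(a near-positivity violation), which destabilizes weighting-based
estimators.
"""

from drate import generate_scenario_dataset, overlap_summary, scenario1, true_propensity

config = scenario1()
cohort = generate_scenario_dataset(config, n=10_000, seed=1)
print(f"cohort: {len(cohort)} records; P(A=1) = {cohort.a.mean():.3f}; "
      f"P(Y=1) = {cohort.y.mean():.3f}\n")

for severity in (1.0, 2.0):
    cfg = scenario1(positivity_severity=severity)
    g0 = true_propensity(cfg, cohort[["w1", "w2", "w3", "w4"]])
    s = overlap_summary(g0, cohort.a.to_numpy())
    o = s["overall"]
    print(f"severity {severity}: g0 min {o['min']:.4f} | p1 {o['p1']:.4f} | "
          f"median {o['p50']:.3f} | max {o['max']:.3f} | "
          f"near-positivity flag: {s['near_positivity']}")
print("\nAt the default severity the lower percentile sits near 0.03 - "
      "large weights but estimable; doubling the severity drives "
      "propensities below 1%, where inverse-probability weights explode.")
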