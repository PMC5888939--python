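import numpy as np
import pandas as pd
import pytest

from drate.datagen import scenario1, generate_scenario_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def s1_cohort():
    """One moderate scenario-1 cohort shared across read-only tests."""
    return generate_scenario_dataset(scenario1(), 2000, seed=42)


@pytest.fixture()
def randomized_cohort(rng):
    """A cohort with treatment independent of covariates and a known
    constant risk difference on the logit scale."""
    n = 5000
    rng = np.random.default_rng(7)
    w1 = rng.integers(1, 6, n).astype(float)
    w2 = rng.random(n)
    w3 = rng.integers(1, 5, n).astype(float)
    w4 = rng.binomial(1, 0.5, n).astype(float)
    a = rng.binomial(1, 0.5, n)
    p = 1 / (1 + np.exp(-(-0.8 + 0.6 * a + 0.2 * w2 + 0.1 * w4)))
    y = (rng.random(n) < p).astype(int)
    return pd.DataFrame({"w1": w1, "w2": w2, "w3": w3, "w4": w4, "a": a, "y": y})
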