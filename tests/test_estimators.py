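"""The four ATE estimators and influence-curve inference."""

import numpy as np
import pandas as pd
import pytest

from drate.estimators import (
    EstimationError,
    PositivityError,
    aiptw_ate,
    influence_se,
    iptw_ra_ate,
    naive_ate,
    tmle_ate,
)
from drate.nuisance import ModelSpec, NuisanceEstimates, expit, logit

TSPEC = ModelSpec("treatment", ("w1", "w2", "w3", "w4"))
OSPEC = ModelSpec("outcome", ("w1", "w2", "w3", "w4"))


def _toy_cohort():
    """Six printed records used by the linear-algebra oracle."""
    return pd.DataFrame(
        {
            "w1": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0],
            "w2": [0.1, 0.5, 0.9, 0.2, 0.6, 0.8],
            "w3": [1.0, 2.0, 1.0, 2.0, 1.0, 2.0],
            "w4": [0.0, 1.0, 0.0, 1.0, 0.0, 1.0],
            "a": [0, 0, 0, 1, 1, 1],
            "y": [0, 1, 1, 0, 1, 1],
        }
    )


class TestInfluenceSE:
    def test_constant_ic_zero_se(self):
        assert influence_se(np.full(10, 3.0)) == 0.0

    def test_two_point_hand_value(self):
        # var((-1,1), ddof=1) = 2; se = sqrt(2/2) / sqrt(2)... = 1
        assert influence_se(np.array([-1.0, 1.0])) == pytest.approx(1.0)

    def test_needs_two_observations(self):
        with pytest.raises(ValueError):
            influence_se(np.array([1.0]))

    def test_aiptw_se_matches_bootstrap(self):
        """Oracle: nonparametric bootstrap of the AIPTW point estimate
        on a 200-row fixture, 2,000 resamples."""
        from drate.datagen import generate_scenario_dataset, scenario1

        d = generate_scenario_dataset(scenario1(), 200, seed=5)
        est = aiptw_ate(d, TSPEC, OSPEC, ps_tol=1e-6)
        rng = np.random.default_rng(99)
        boots = []
        for _ in range(2000):
            idx = rng.integers(0, 200, 200)
            db = d.iloc[idx].reset_index(drop=True)
            try:
                boots.append(aiptw_ate(db, TSPEC, OSPEC, ps_tol=1e-6).psi)
            except EstimationError:
                continue
        boot_se = np.std(boots, ddof=1)
        assert est.se == pytest.approx(boot_se, rel=0.15)


class TestNaive:
    def test_randomized_no_covariates_equals_difference_in_means(self):
        rng = np.random.default_rng(1)
        n = 400
        a = rng.binomial(1, 0.5, n)
        y = rng.binomial(1, np.where(a == 1, 0.6, 0.4))
        d = pd.DataFrame({"w1": np.ones(n), "a": a, "y": y})
        est = naive_ate(d, ModelSpec("outcome", ("a",)))  # y ~ a only
        dim = y[a == 1].mean() - y[a == 0].mean()
        assert est.psi == pytest.approx(dim, abs=1e-10)

    def test_six_row_toy_matches_normal_equations(self):
        """Linear-algebra oracle: solve X'X b = X'y directly."""
        d = _toy_cohort()
        X = np.column_stack(
            [np.ones(6), d.a, d.w1, d.w2, d.w3, d.w4]
        )
        beta = np.linalg.solve(X.T @ X, X.T @ d.y.to_numpy(float))
        est = naive_ate(d)
        assert est.psi == pytest.approx(beta[1], abs=1e-10)

    def test_ci_identity(self, s1_cohort):
        est = naive_ate(s1_cohort)
        assert est.ci95[0] == pytest.approx(est.psi - 1.96 * est.se)
        assert est.ci95[1] == pytest.approx(est.psi + 1.96 * est.se)

    def test_one_arm_data_rejected(self):
        d = _toy_cohort().assign(a=1)
        with pytest.raises(EstimationError):
            naive_ate(d)


class TestIPTWRA:
    def test_randomized_near_constant_weights_match_unweighted_standardization(self):
        """With treatment independent of W the weights are ~constant,
        so the estimate equals plain per-arm standardization."""
        rng = np.random.default_rng(3)
        n = 4000
        w = rng.random(n)
        a = rng.binomial(1, 0.5, n)
        y = rng.binomial(1, expit(-0.5 + 0.8 * a + 0.5 * w))
        d = pd.DataFrame({"w1": w, "a": a, "y": y})
        tspec = ModelSpec("treatment", ("w1",))
        ospec = ModelSpec("outcome", ("w1",))
        est = iptw_ra_ate(d, tspec, ospec)
        # unweighted per-arm logistic standardization oracle
        from drate.nuisance import build_design_matrix, fit_logistic

        spec_arm = ModelSpec("outcome", ("w1",), include_treatment_main=False)
        X, _ = build_design_matrix(d, spec_arm)
        m = {}
        for arm in (0, 1):
            fit = fit_logistic(X[a == arm], y[a == arm].astype(float))
            m[arm] = fit.predict(X)
        oracle = np.mean(m[1] - m[0])
        assert est.psi == pytest.approx(oracle, abs=0.01)

    def test_saturated_specs_match_2x2x2_standardization(self):
        """Stratification oracle: with one binary covariate and
        saturated models the estimate is the nonparametric
        standardized risk difference from the 2x2x2 table."""
        rng = np.random.default_rng(4)
        n = 3000
        w = rng.binomial(1, 0.4, n).astype(float)
        a = rng.binomial(1, np.where(w == 1, 0.7, 0.3))
        y = rng.binomial(1, 0.2 + 0.3 * a + 0.25 * w)
        d = pd.DataFrame({"w1": w, "a": a, "y": y})
        spec = ModelSpec("treatment", ("w1",))
        est = iptw_ra_ate(d, spec, ModelSpec("outcome", ("w1",)))
        oracle = 0.0
        for v in (0.0, 1.0):
            pw = np.mean(w == v)
            p1 = y[(a == 1) & (w == v)].mean()
            p0 = y[(a == 0) & (w == v)].mean()
            oracle += pw * (p1 - p0)
        assert est.psi == pytest.approx(oracle, abs=1e-6)

    def test_positivity_error_names_offender_count(self, s1_cohort):
        with pytest.raises(PositivityError, match=r"\d+ fitted propensity"):
            iptw_ra_ate(s1_cohort, TSPEC, OSPEC, ps_tol=0.4)

    def test_stacked_se_close_to_bootstrap(self):
        from drate.datagen import generate_scenario_dataset, scenario1

        d = generate_scenario_dataset(scenario1(), 500, seed=9)
        est = iptw_ra_ate(d, TSPEC, OSPEC)
        rng = np.random.default_rng(17)
        boots = []
        for _ in range(500):
            idx = rng.integers(0, 500, 500)
            try:
                boots.append(
                    iptw_ra_ate(d.iloc[idx].reset_index(drop=True), TSPEC, OSPEC).psi
                )
            except EstimationError:
                continue
        assert est.se == pytest.approx(np.std(boots, ddof=1), rel=0.25)

    def test_fixed_weight_se_smaller_than_stacked_input_noise(self, s1_cohort):
        stacked = iptw_ra_ate(s1_cohort, TSPEC, OSPEC, se_method="stacked")
        fixed = iptw_ra_ate(s1_cohort, TSPEC, OSPEC, se_method="fixed")
        assert stacked.psi == pytest.approx(fixed.psi)
        assert fixed.se > 0


class TestAIPTW:
    def test_hand_formula_on_four_rows(self):
        """Hand oracle: psi computed term by term from the printed
        formula with fixed nuisance values."""
        d = pd.DataFrame(
            {"w1": [1.0, 1.0, 2.0, 2.0], "a": [1, 0, 1, 0], "y": [1, 0, 0, 1]}
        )
        g = np.array([0.8, 0.8, 0.2, 0.2])
        q1 = np.full(4, 0.5)
        q0 = np.full(4, 0.5)
        nuis = NuisanceEstimates(g=g, q_obs=np.full(4, 0.5), q1=q1, q0=q0)
        est = aiptw_ate(d, TSPEC, OSPEC, ps_tol=1e-8, nuisance=nuis)
        a, y = d.a.to_numpy(float), d.y.to_numpy(float)
        hand = np.mean(q1 - q0 + a * (y - q1) / g - (1 - a) * (y - q0) / (1 - g))
        assert est.psi == pytest.approx(hand, abs=1e-12)

    def test_zero_residual_reduces_to_plug_in(self):
        """With q equal to the observed outcomes the augmentation
        vanishes and psi is the plug-in mean of q1 - q0."""
        rng = np.random.default_rng(6)
        n = 50
        y = rng.binomial(1, 0.5, n).astype(float)
        a = rng.binomial(1, 0.5, n)
        q_obs = y.copy()
        q1 = np.where(a == 1, y, 0.3)
        q0 = np.where(a == 0, y, 0.6)
        nuis = NuisanceEstimates(
            g=np.full(n, 0.5), q_obs=q_obs, q1=q1, q0=q0
        )
        d = pd.DataFrame({"w1": np.ones(n), "a": a, "y": y})
        est = aiptw_ate(d, TSPEC, OSPEC, nuisance=nuis)
        assert est.psi == pytest.approx(np.mean(q1 - q0), abs=1e-12)

    def test_positivity_tolerance_enforced(self):
        d = _toy_cohort()
        nuis = NuisanceEstimates(
            g=np.array([1e-7, 0.5, 0.5, 0.5, 0.5, 0.5]),
            q_obs=np.full(6, 0.5), q1=np.full(6, 0.5), q0=np.full(6, 0.5),
        )
        with pytest.raises(PositivityError):
            aiptw_ate(d, TSPEC, OSPEC, ps_tol=1e-5, nuisance=nuis)

    def test_se_is_summand_sd_over_sqrt_n(self):
        d = _toy_cohort()
        g = np.full(6, 0.5)
        q1, q0 = np.full(6, 0.6), np.full(6, 0.4)
        nuis = NuisanceEstimates(g=g, q_obs=np.full(6, 0.5), q1=q1, q0=q0)
        est = aiptw_ate(d, TSPEC, OSPEC, nuisance=nuis)
        a, y = d.a.to_numpy(float), d.y.to_numpy(float)
        s = q1 - q0 + a * (y - q1) / g - (1 - a) * (y - q0) / (1 - g)
        assert est.se == pytest.approx(np.std(s, ddof=1) / np.sqrt(6))


class TestTMLE:
    def test_fixed_point_when_initial_fit_solves_score_equation(self):
        """With constant g and arm-specific means as the initial fit,
        the efficient-score equations already hold, so the fluctuation
        is a no-op and psi is the initial plug-in mean."""
        rng = np.random.default_rng(8)
        n = 100
        a = rng.binomial(1, 0.5, n)
        y = rng.binomial(1, np.where(a == 1, 0.65, 0.35), n).astype(float)
        q1 = np.full(n, y[a == 1].mean())
        q0 = np.full(n, y[a == 0].mean())
        q_obs = np.where(a == 1, q1, q0)
        nuis = NuisanceEstimates(g=np.full(n, 0.5), q_obs=q_obs, q1=q1, q0=q0)
        d = pd.DataFrame({"w1": np.ones(n), "a": a, "y": y})
        est, fl = tmle_ate(d, nuisance=nuis)
        assert abs(fl.epsilon[0]) < 1e-8 and abs(fl.epsilon[1]) < 1e-8
        assert est.psi == pytest.approx(
            y[a == 1].mean() - y[a == 0].mean(), abs=1e-8
        )

    def test_five_row_toy_matches_grid_search(self):
        """Grid-search oracle: maximize the fluctuation likelihood
        over (eps1, eps0) directly and compare."""
        d = pd.DataFrame(
            {"w1": [1.0] * 5, "a": [1, 1, 0, 0, 0], "y": [1, 0, 1, 0, 0]}
        )
        g = np.array([0.6, 0.3, 0.4, 0.5, 0.2])
        q1 = np.array([0.7, 0.4, 0.5, 0.6, 0.3])
        q0 = np.array([0.5, 0.3, 0.6, 0.4, 0.2])
        a, y = d.a.to_numpy(float), d.y.to_numpy(float)
        q_obs = np.where(a == 1, q1, q0)
        nuis = NuisanceEstimates(g=g, q_obs=q_obs, q1=q1, q0=q0)
        est, fl = tmle_ate(d, nuisance=nuis, g_bounds=(0.0, 1.0))

        h1, h0 = a / g, -(1 - a) / (1 - g)
        off = logit(q_obs)

        def loglik(e1, e0):
            mu = expit(off + e1 * h1 + e0 * h0)
            return np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu))

        grid = np.linspace(-2, 2, 4001)
        best1 = grid[np.argmax([loglik(e, 0.0) for e in grid])]
        best0 = grid[np.argmax([loglik(best1, e) for e in grid])]
        assert fl.epsilon[0] == pytest.approx(best1, abs=1e-3)
        assert fl.epsilon[1] == pytest.approx(best0, abs=1e-3)
        q1s = expit(logit(q1) + best1 / g)
        q0s = expit(logit(q0) - best0 / (1 - g))
        assert est.psi == pytest.approx(np.mean(q1s - q0s), abs=1e-4)

    def test_mean_ic_is_zero_after_convergence(self, s1_cohort):
        est, _ = tmle_ate(s1_cohort, treatment_spec=TSPEC, outcome_spec=OSPEC)
        assert abs(est.diagnostics["mean_ic"]) < 1e-8

    def test_substitution_estimate_respects_range(self, s1_cohort):
        est, _ = tmle_ate(s1_cohort, treatment_spec=TSPEC, outcome_spec=OSPEC)
        assert -1.0 <= est.psi <= 1.0

    def test_adversarial_fixture_aiptw_escapes_range_tmle_does_not(self):
        """Near-positivity fixture on which the estimating-equation
        estimator leaves [-1, 1] while the substitution estimator
        cannot."""
        n = 20
        rng = np.random.default_rng(13)
        a = np.zeros(n, dtype=int)
        a[0] = 1
        y = rng.binomial(1, 0.5, n)
        y[0] = 1
        g = np.full(n, 0.5)
        g[0] = 1e-4  # one treated subject with a vanishing propensity
        q1 = np.full(n, 0.4)
        q0 = np.full(n, 0.4)
        q_obs = np.where(a == 1, q1, q0)
        nuis = NuisanceEstimates(g=g, q_obs=q_obs, q1=q1, q0=q0)
        d = pd.DataFrame({"w1": np.ones(n), "a": a, "y": y})
        aipw = aiptw_ate(d, TSPEC, OSPEC, ps_tol=1e-6, nuisance=nuis)
        assert aipw.psi > 1.0
        tm, _ = tmle_ate(d, nuisance=nuis)
        assert -1.0 <= tm.psi <= 1.0

    def test_single_epsilon_variant_close_to_two_epsilon(self, s1_cohort):
        two, _ = tmle_ate(s1_cohort, treatment_spec=TSPEC, outcome_spec=OSPEC)
        one, _ = tmle_ate(
            s1_cohort, treatment_spec=TSPEC, outcome_spec=OSPEC, single_epsilon=True
        )
        assert one.psi == pytest.approx(two.psi, abs=0.02)

    def test_empty_arm_rejected(self):
        d = _toy_cohort().assign(a=0)
        with pytest.raises(EstimationError):
            tmle_ate(d, treatment_spec=TSPEC, outcome_spec=OSPEC)


class TestRandomizationAgreement:
    def test_all_estimators_match_difference_in_means(self, randomized_cohort):
        """Under randomization every estimator targets the same
        quantity; each should agree with the difference in means
        within three standard errors."""
        d = randomized_cohort
        y, a = d.y.to_numpy(float), d.a.to_numpy(float)
        dim = y[a == 1].mean() - y[a == 0].mean()
        dim_se = np.sqrt(
            y[a == 1].var() / (a == 1).sum() + y[a == 0].var() / (a == 0).sum()
        )
        estimates = {
            "naive": naive_ate(d),
            "iptw_ra": iptw_ra_ate(d, TSPEC, OSPEC),
            "aiptw": aiptw_ate(d, TSPEC, OSPEC),
            "tmle": tmle_ate(d, treatment_spec=TSPEC, outcome_spec=OSPEC)[0],
            "tmle_sl": tmle_ate(d[["w1", "w2", "w3", "w4", "a", "y"]], v=5, seed=3)[0],
        }
        for name, est in estimates.items():
            se = max(est.se, dim_se)
            assert abs(est.psi - dim) < 3 * se, name
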