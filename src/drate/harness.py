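"""Monte Carlo engine benchmarking the ATE estimators.

Each replication draws a fresh cohort from the configured generating
process, applies every configured estimator, and records point
estimate, influence-curve SE and 95% CI.  Estimator failures (e.g.
positivity errors under extreme weights) are captured per replication,
never fatal.  Aggregation produces the standard benchmarking metrics:
mean estimate, SD across replications, absolute and relative bias,
RMSE, and CI coverage of the true risk difference.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import estimators as est
from .datagen import DGPConfig, compute_true_ate, generate_scenario_dataset
from .model_selection import bfit_select, enumerate_candidates
from .nuisance import ModelSpec

__all__ = [
    "EstimatorSetting",
    "MCConfig",
    "PerformanceSummary",
    "run_replicate",
    "run_monte_carlo",
    "summarize_estimates",
    "report_table",
    "default_estimators",
]

DEFAULT_COVARIATES = ("w1", "w2", "w3", "w4")


@dataclass(frozen=True)
class EstimatorSetting:
    """One estimator configuration inside the Monte Carlo.

    ``spec_mode`` selects how nuisance specifications are chosen per
    replication: "correct" derives them from the generating model,
    "misspecified" uses main terms only, "bfit" selects by AIC/BIC
    over the order-2 candidate ladder, "sl" (TMLE) uses the super
    learner.
    """

    label: str
    method: str  # naive | iptw_ra | aiptw | tmle
    spec_mode: str = "correct"  # correct | misspecified | bfit | sl
    ps_tol: float = 1e-5
    g_bounds: tuple[float, float] = (0.025, 0.975)
    sl_library: tuple[str, ...] = ("sl_step", "sl_glm", "sl_glm_interaction")
    sl_folds: int = 10
    bfit_criterion: str = "aic"

    def __post_init__(self):
        if self.method not in ("naive", "iptw_ra", "aiptw", "tmle"):
            raise ValueError(f"unknown method {self.method!r}")


def _dgp_specs(dgp: DGPConfig) -> tuple[ModelSpec, ModelSpec]:
    """The correctly specified treatment/outcome specs implied by a
    generating model's coefficient dictionaries."""
    t_terms = tuple(k for k in dgp.alpha if k != "intercept")
    o_terms = tuple(k for k in dgp.beta if k not in ("intercept", "a"))
    return ModelSpec("treatment", t_terms), ModelSpec("outcome", o_terms)


def _main_terms_specs() -> tuple[ModelSpec, ModelSpec]:
    return (
        ModelSpec("treatment", DEFAULT_COVARIATES),
        ModelSpec("outcome", DEFAULT_COVARIATES),
    )


@dataclass(frozen=True)
class MCConfig:
    """Design of one Monte Carlo experiment."""

    dgp: DGPConfig
    n_per_rep: int = 1000
    reps: int = 1000
    estimators: tuple[EstimatorSetting, ...] = ()
    master_seed: int = 0
    true_ate_mc: int = 1_000_000

    def __post_init__(self):
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if not self.estimators:
            raise ValueError("estimator list must be non-empty")


def default_estimators(profile: str = "full") -> tuple[EstimatorSetting, ...]:
    """The benchmark's standard estimator battery.

    The "scaled" profile reduces super-learner folds to 5 for
    desk-scale runs; estimator settings are otherwise identical.
    """
    folds = 5 if profile == "scaled" else 10
    return (
        EstimatorSetting("naive", "naive"),
        EstimatorSetting("iptw_ra", "iptw_ra"),
        EstimatorSetting("aiptw", "aiptw"),
        EstimatorSetting("tmle", "tmle", spec_mode="sl", sl_folds=folds),
    )


def _rep_seed(master_seed: int, rep_index: int) -> int:
    ss = np.random.SeedSequence([int(master_seed), int(rep_index)])
    return int(ss.generate_state(1)[0] % (2**31))


def _resolve_specs(setting: EstimatorSetting, dgp: DGPConfig, data: pd.DataFrame):
    if setting.spec_mode == "correct":
        return _dgp_specs(dgp)
    if setting.spec_mode == "misspecified":
        return _main_terms_specs()
    if setting.spec_mode == "bfit":
        cands_t = enumerate_candidates(list(DEFAULT_COVARIATES), 2, "treatment")
        cands_o = enumerate_candidates(list(DEFAULT_COVARIATES), 2, "outcome")
        sel_t = bfit_select(data, "a", cands_t, setting.bfit_criterion)
        sel_o = bfit_select(data, "y", cands_o, setting.bfit_criterion)
        return sel_t.chosen_spec, sel_o.chosen_spec
    raise ValueError(f"spec_mode {setting.spec_mode!r} needs no parametric specs")


def _apply_estimator(
    setting: EstimatorSetting, data: pd.DataFrame, dgp: DGPConfig, seed: int
) -> est.ATEEstimate:
    if setting.method == "naive":
        return est.naive_ate(data)
    if setting.method == "tmle" and setting.spec_mode == "sl":
        res, _ = est.tmle_ate(
            data[["w1", "w2", "w3", "w4", "a", "y"]],
            sl_library=list(setting.sl_library),
            g_bounds=setting.g_bounds,
            v=setting.sl_folds,
            seed=seed,
        )
        return res
    tspec, ospec = _resolve_specs(setting, dgp, data)
    if setting.method == "iptw_ra":
        return est.iptw_ra_ate(data, tspec, ospec, ps_tol=setting.ps_tol)
    if setting.method == "aiptw":
        return est.aiptw_ate(data, tspec, ospec, ps_tol=setting.ps_tol)
    if setting.method == "tmle":
        res, _ = est.tmle_ate(
            data,
            treatment_spec=tspec,
            outcome_spec=ospec,
            g_bounds=setting.g_bounds,
        )
        return res
    raise ValueError(setting.method)


def run_replicate(config: MCConfig, rep_index: int) -> list[dict]:
    """Run every configured estimator on one seeded replication.

    Failures are recorded per estimator (``failed=True`` with the
    reason); other estimators on the same dataset are unaffected.
    """
    seed = _rep_seed(config.master_seed, rep_index)
    data = generate_scenario_dataset(config.dgp, config.n_per_rep, seed)
    rows = []
    for setting in config.estimators:
        row = {"rep": rep_index, "estimator": setting.label, "seed": seed}
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                r = _apply_estimator(setting, data, config.dgp, seed)
            row.update(
                psi=r.psi, se=r.se, ci_lo=r.ci95[0], ci_hi=r.ci95[1],
                failed=False, error="",
            )
        except est.EstimationError as e:
            row.update(
                psi=np.nan, se=np.nan, ci_lo=np.nan, ci_hi=np.nan,
                failed=True, error=str(e),
            )
        rows.append(row)
    return rows


@dataclass
class PerformanceSummary:
    """Benchmark metrics per estimator, plus the truth they refer to."""

    true_ate: float
    table: pd.DataFrame  # one row per estimator
    raw: pd.DataFrame  # one row per (rep, estimator)

    def row(self, label: str) -> pd.Series:
        return self.table.set_index("estimator").loc[label]


def summarize_estimates(
    psis: np.ndarray,
    ci_lo: np.ndarray,
    ci_hi: np.ndarray,
    psi0: float,
) -> dict:
    """The benchmark metrics for one estimator's replication draws."""
    psis = np.asarray(psis, dtype=float)
    mean_psi = float(np.mean(psis))
    sd_psi = float(np.std(psis, ddof=1)) if len(psis) > 1 else 0.0
    abs_bias = abs(mean_psi - psi0)
    return {
        "mean_psi": mean_psi,
        "sd_psi": sd_psi,
        "abs_bias": abs_bias,
        "rel_bias_pct": 100.0 * abs_bias / abs(psi0) if psi0 != 0 else np.nan,
        "rmse": float(np.sqrt(np.mean((psis - psi0) ** 2))),
        "coverage_pct": 100.0 * float(np.mean((ci_lo <= psi0) & (psi0 <= ci_hi))),
        "n_used": int(len(psis)),
    }


def run_monte_carlo(
    config: MCConfig,
    true_ate: float | None = None,
    progress: bool = False,
) -> PerformanceSummary:
    """Run the full experiment and aggregate the metrics.

    ``true_ate`` short-circuits the plug-in truth computation when the
    caller already knows it.  An estimator failing in more than 20% of
    replications is flagged unreliable in the summary table.
    """
    psi0 = (
        compute_true_ate(config.dgp, config.true_ate_mc, seed=config.master_seed)
        if true_ate is None
        else float(true_ate)
    )
    all_rows = []
    for r in range(config.reps):
        all_rows.extend(run_replicate(config, r))
        if progress and (r + 1) % 50 == 0:
            print(f"  replication {r + 1}/{config.reps}", flush=True)
    raw = pd.DataFrame(all_rows)
    out = []
    for setting in config.estimators:
        sub = raw[raw["estimator"] == setting.label]
        ok = sub[~sub["failed"]]
        n_failed = int(sub["failed"].sum())
        if len(ok) == 0:
            metrics = {k: np.nan for k in (
                "mean_psi", "sd_psi", "abs_bias", "rel_bias_pct",
                "rmse", "coverage_pct")} | {"n_used": 0}
        else:
            metrics = summarize_estimates(
                ok["psi"].to_numpy(), ok["ci_lo"].to_numpy(),
                ok["ci_hi"].to_numpy(), psi0,
            )
        out.append(
            {
                "estimator": setting.label,
                **metrics,
                "n_failed": n_failed,
                "unreliable": n_failed > 0.2 * config.reps,
            }
        )
    return PerformanceSummary(true_ate=psi0, table=pd.DataFrame(out), raw=raw)


def report_table(summary: PerformanceSummary) -> pd.DataFrame:
    """Benchmark table with stable formatting: ATE (SD), absolute
    bias (4 decimals), relative bias and coverage (1 decimal), RMSE."""
    t = summary.table
    if len(t) == 0:
        return pd.DataFrame(
            columns=[
                "estimator", "ate_sd", "abs_bias", "rel_bias_pct",
                "rmse", "coverage_pct", "n_failed",
            ]
        )
    out = pd.DataFrame(
        {
            "estimator": t["estimator"],
            "ate_sd": [
                f"{m:.4f} ({s:.3f})" if np.isfinite(m) else "failed"
                for m, s in zip(t["mean_psi"], t["sd_psi"])
            ],
            "abs_bias": t["abs_bias"].round(4),
            "rel_bias_pct": t["rel_bias_pct"].round(1),
            "rmse": t["rmse"].round(4),
            "coverage_pct": t["coverage_pct"].round(1),
            "n_failed": t["n_failed"],
        }
    )
    return out


def save_run(summary: PerformanceSummary, config: MCConfig, out_dir) -> None:
    """Write raw estimates, the summary table and full provenance."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary.raw.to_csv(out / "raw_estimates.csv", index=False)
    report_table(summary).to_csv(out / "summary.csv", index=False)
    prov = {
        "true_ate": summary.true_ate,
        "n_per_rep": config.n_per_rep,
        "reps": config.reps,
        "master_seed": config.master_seed,
        "dgp": {
            "scenario_id": config.dgp.scenario_id,
            "alpha": config.dgp.alpha,
            "beta": config.dgp.beta,
            "positivity_severity": config.dgp.positivity_severity,
            "covariate_laws": config.dgp.covariate_laws,
        },
        "estimators": [
            {
                "label": s.label, "method": s.method, "spec_mode": s.spec_mode,
                "ps_tol": s.ps_tol, "g_bounds": list(s.g_bounds),
                "sl_folds": s.sl_folds,
            }
            for s in config.estimators
        ],
    }
    (out / "config.json").write_text(json.dumps(prov, indent=2))
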