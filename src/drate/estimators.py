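"""ATE estimators: naive regression adjustment, IPTW-RA, AIPTW, TMLE.

The target parameter is the average treatment effect on the risk scale,
psi = E[Y(1)] - E[Y(0)], for a binary exposure and binary outcome.
All estimators report an influence-curve (or sandwich) standard error
and a normal-approximation 95% confidence interval.

Estimator notes
---------------
* ``naive_ate`` is the coefficient on A from a linear-probability
  regression of Y on A and main-effect covariate terms, with an HC1
  robust SE — a conditional-variance-weighted effect that is biased for
  the ATE under effect heterogeneity and poor overlap.
* ``iptw_ra_ate`` fits the propensity model, then inverse-probability-
  weighted logistic outcome regressions separately per arm, and
  standardizes the two arm predictions over the whole sample.  Its SE
  comes from the stacked M-estimation sandwich covering the propensity
  and both outcome fits (a fixed-weight variant is available).
* ``aiptw_ate`` solves the efficient estimating equation in one step;
  the point estimate may legitimately fall outside [-1, 1] under
  near-positivity violations.
* ``tmle_ate`` updates an initial outcome fit along a logistic
  fluctuation in the clever covariates (A/g, -(1-A)/(1-g)) and plugs
  the updated predictions in; the estimate is a substitution estimator
  and always respects [-1, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import superlearner as sl
from .nuisance import (
    ModelSpec,
    NuisanceEstimates,
    bound_propensity,
    build_design_matrix,
    expit,
    fit_logistic,
    logit,
    overlap_summary,
    parse_term,
)

__all__ = [
    "ATEEstimate",
    "FluctuationResult",
    "PositivityError",
    "EstimationError",
    "naive_ate",
    "iptw_ra_ate",
    "aiptw_ate",
    "tmle_ate",
    "influence_se",
]

Z95 = 1.96
QTRUNC = 1e-6


class EstimationError(RuntimeError):
    """Estimation cannot proceed (e.g. an empty treatment arm)."""


class PositivityError(EstimationError):
    """Fitted propensity scores violate the weight tolerance."""


@dataclass
class ATEEstimate:
    method: str
    psi: float
    se: float
    ci95: tuple[float, float] = (np.nan, np.nan)
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.se < 0:
            raise ValueError("standard error must be >= 0")
        self.ci95 = (self.psi - Z95 * self.se, self.psi + Z95 * self.se)


@dataclass
class FluctuationResult:
    epsilon: tuple[float, float]
    h1: np.ndarray
    h0: np.ndarray
    q1_star: np.ndarray
    q0_star: np.ndarray
    converged: bool


def influence_se(ic: np.ndarray) -> float:
    """Standard error from an estimated influence curve:
    sqrt(Var(ic)/n) with the sample (ddof=1) variance."""
    ic = np.asarray(ic, dtype=float)
    if len(ic) < 2:
        raise ValueError("influence-curve SE needs n >= 2")
    return float(np.sqrt(np.var(ic, ddof=1) / len(ic)))


def _check_arms(a: np.ndarray):
    if a.sum() == 0 or a.sum() == len(a):
        raise EstimationError("both treatment arms must be non-empty")


def naive_ate(cohort: pd.DataFrame, outcome_spec: ModelSpec | None = None) -> ATEEstimate:
    """Main-terms linear-probability regression; psi is the coefficient
    on A, SE is heteroskedasticity-robust (HC1)."""
    a = cohort["a"].to_numpy(dtype=float)
    y = cohort["y"].to_numpy(dtype=float)
    _check_arms(a)
    terms = tuple(
        t for t in (outcome_spec.terms if outcome_spec else ("w1", "w2", "w3", "w4"))
        if t != "a"
    )
    cols = [np.ones(len(cohort)), a]
    names = ["(intercept)", "a"]
    for t in terms:
        col = np.ones(len(cohort))
        for c in parse_term(t):
            col = col * cohort[c].to_numpy(dtype=float)
        cols.append(col)
        names.append(t)
    X = np.column_stack(cols)
    res = sm.OLS(y, X).fit(cov_type="HC1")
    return ATEEstimate(
        method="naive",
        psi=float(res.params[1]),
        se=float(res.bse[1]),
        diagnostics={"terms": names},
    )


def _fit_propensity(cohort, treatment_spec, ps_tol, bounds=None):
    a = cohort["a"].to_numpy(dtype=float)
    Xg, g_names = build_design_matrix(cohort, treatment_spec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        gfit = fit_logistic(Xg, a, compute_cov=True, column_names=g_names)
    g = gfit.predict(Xg)
    if bounds is not None:
        g = bound_propensity(g, *bounds)
    if ps_tol is not None:
        bad = int(np.sum((g < ps_tol) | (g > 1 - ps_tol)))
        if bad:
            raise PositivityError(
                f"{bad} fitted propensity scores outside ({ps_tol:g}, "
                f"{1 - ps_tol:g}); near-positivity violation"
            )
    return gfit, Xg, g


def iptw_ra_ate(
    cohort: pd.DataFrame,
    treatment_spec: ModelSpec,
    outcome_spec: ModelSpec,
    ps_tol: float = 1e-5,
    stabilized: bool = False,
    se_method: str = "stacked",
) -> ATEEstimate:
    """Inverse-probability-weighted regression adjustment.

    Weighted logistic outcome regressions per arm, standardized over
    the full sample.  ``se_method`` "stacked" propagates propensity and
    outcome estimation through the M-estimation sandwich; "fixed"
    treats the weights and outcome fits as known (influence of the
    standardization step only).
    """
    a = cohort["a"].to_numpy(dtype=float)
    y = cohort["y"].to_numpy(dtype=float)
    _check_arms(a)
    gfit, Xg, g = _fit_propensity(cohort, treatment_spec, ps_tol)

    wts = np.where(a == 1, 1.0 / g, 1.0 / (1.0 - g))
    if stabilized:
        wts = np.where(a == 1, a.mean() / g, (1 - a.mean()) / (1.0 - g))

    # outcome spec without a forced treatment main effect: arms are
    # modeled separately (implicit full treatment interaction)
    spec_arm = ModelSpec("outcome", outcome_spec.terms, include_treatment_main=False)
    Xq, q_names = build_design_matrix(cohort, spec_arm)
    fits = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for arm in (1, 0):
            mask = a == arm
            fits[arm] = fit_logistic(
                Xq[mask], y[mask], weights=wts[mask], column_names=q_names
            )
    m1 = fits[1].predict(Xq)
    m0 = fits[0].predict(Xq)
    psi = float(np.mean(m1 - m0))

    if se_method == "stacked":
        se = _iptw_ra_sandwich_se(a, y, g, Xg, Xq, m1, m0, psi, stabilized)
    elif se_method == "fixed":
        se = influence_se(m1 - m0 - psi)
    else:
        raise ValueError(f"unknown se_method {se_method!r}")

    return ATEEstimate(
        method="iptw_ra",
        psi=psi,
        se=se,
        diagnostics={
            "ps_summary": overlap_summary(g, a),
            "converged": gfit.converged and fits[1].converged and fits[0].converged,
            "max_weight": float(wts.max()),
        },
    )


def _iptw_ra_sandwich_se(a, y, g, Xg, Xq, m1, m0, psi, stabilized):
    """Sandwich variance of the stacked estimating equations:
    propensity score, arm-1 weighted fit, arm-0 weighted fit, and the
    standardization equation."""
    n = len(a)
    kg, kq = Xg.shape[1], Xq.shape[1]
    p = kg + 2 * kq + 1
    w1 = a / g if not stabilized else a * a.mean() / g
    w0 = (1 - a) / (1 - g) if not stabilized else (1 - a) * (1 - a.mean()) / (1 - g)

    phi = np.zeros((n, p))
    phi[:, :kg] = Xg * (a - g)[:, None]
    phi[:, kg : kg + kq] = Xq * (w1 * (y - m1))[:, None]
    phi[:, kg + kq : kg + 2 * kq] = Xq * (w0 * (y - m0))[:, None]
    phi[:, -1] = m1 - m0 - psi

    A = np.zeros((p, p))
    sg = g * (1 - g)
    A[:kg, :kg] = (Xg * sg[:, None]).T @ Xg / n
    # d/dgamma of the weighted arm scores (weights depend on gamma)
    c1 = a * (y - m1) * (1 - g) / g if not stabilized else a * a.mean() * (y - m1) * (1 - g) / g
    A[kg : kg + kq, :kg] = -(Xq * c1[:, None]).T @ Xg / n
    c0 = (1 - a) * (y - m0) * g / (1 - g)
    if stabilized:
        c0 = c0 * (1 - a.mean())
    A[kg + kq : kg + 2 * kq, :kg] = (Xq * c0[:, None]).T @ Xg / n
    s1 = w1 * m1 * (1 - m1)
    A[kg : kg + kq, kg : kg + kq] = (Xq * s1[:, None]).T @ Xq / n
    s0 = w0 * m0 * (1 - m0)
    A[kg + kq : kg + 2 * kq, kg + kq : kg + 2 * kq] = (Xq * s0[:, None]).T @ Xq / n
    A[-1, kg : kg + kq] = -(m1 * (1 - m1)) @ Xq / n
    A[-1, kg + kq : kg + 2 * kq] = (m0 * (1 - m0)) @ Xq / n
    A[-1, -1] = 1.0

    B = phi.T @ phi / n
    Ainv = np.linalg.pinv(A)
    V = Ainv @ B @ Ainv.T / n
    return float(np.sqrt(max(V[-1, -1], 0.0)))


def _fit_outcome_with_a(cohort, outcome_spec):
    """Single logistic outcome model with A as a main term; returns
    (q_obs, q1, q0)."""
    y = cohort["y"].to_numpy(dtype=float)
    spec = ModelSpec("outcome", outcome_spec.terms, include_treatment_main=True)
    Xq, names = build_design_matrix(cohort, spec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        qfit = fit_logistic(Xq, y, column_names=names)
    X1, _ = build_design_matrix(cohort.assign(a=1.0), spec)
    X0, _ = build_design_matrix(cohort.assign(a=0.0), spec)
    return qfit, qfit.predict(Xq), qfit.predict(X1), qfit.predict(X0)


def aiptw_ate(
    cohort: pd.DataFrame,
    treatment_spec: ModelSpec,
    outcome_spec: ModelSpec,
    ps_tol: float = 1e-5,
    nuisance: NuisanceEstimates | None = None,
) -> ATEEstimate:
    """Augmented IPTW (efficient estimating-equation estimator).

    psi = mean[ q1 - q0 + a(y - q1)/g - (1-a)(y - q0)/(1-g) ];
    SE is the sample SD of the summand over sqrt(n).  Raises
    :class:`PositivityError` when fitted propensity scores fall outside
    (ps_tol, 1 - ps_tol), mirroring the weight-tolerance behavior of
    standard AIPTW software.
    """
    a = cohort["a"].to_numpy(dtype=float)
    y = cohort["y"].to_numpy(dtype=float)
    _check_arms(a)
    if nuisance is None:
        gfit, _, g = _fit_propensity(cohort, treatment_spec, ps_tol)
        qfit, q_obs, q1, q0 = _fit_outcome_with_a(cohort, outcome_spec)
        converged = gfit.converged and qfit.converged
    else:
        g, q1, q0 = nuisance.g, nuisance.q1, nuisance.q0
        bad = int(np.sum((g < ps_tol) | (g > 1 - ps_tol)))
        if bad:
            raise PositivityError(
                f"{bad} propensity scores outside ({ps_tol:g}, {1 - ps_tol:g})"
            )
        converged = True

    summand = q1 - q0 + a * (y - q1) / g - (1 - a) * (y - q0) / (1 - g)
    psi = float(np.mean(summand))
    se = influence_se(summand)
    return ATEEstimate(
        method="aiptw",
        psi=psi,
        se=se,
        diagnostics={
            "ps_summary": overlap_summary(g, a),
            "converged": converged,
            "in_range": bool(-1.0 <= psi <= 1.0),
        },
    )


def _fluctuate(y, a, g, q_obs, q1, q0, max_iter=50, tol=1e-10):
    """Logistic fluctuation of the initial outcome fit along the
    clever covariates, by Newton iteration on (eps1, eps0).

    The two clever covariates have disjoint support (h1 lives on the
    treated, h0 on the controls), so the joint intercept-free logistic
    regression with offset logit(Q) separates into two one-dimensional
    problems solved jointly here.
    """
    h1 = a / g
    h0 = -(1 - a) / (1 - g)
    off = logit(q_obs)
    eps = np.zeros(2)
    H = np.column_stack([h1, h0])
    converged = False
    for _ in range(max_iter):
        mu = expit(off + H @ eps)
        grad = H.T @ (y - mu)
        s = mu * (1 - mu)
        info = (H * s[:, None]).T @ H
        try:
            delta = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            delta = np.linalg.lstsq(info, grad, rcond=None)[0]
        eps = eps + delta
        if np.max(np.abs(delta)) < tol:
            converged = True
            break
    if not np.all(np.isfinite(eps)):
        raise EstimationError("fluctuation step diverged")
    q1_star = expit(logit(q1) + eps[0] / g)
    q0_star = expit(logit(q0) - eps[1] / (1 - g))
    return FluctuationResult(
        epsilon=(float(eps[0]), float(eps[1])),
        h1=h1,
        h0=h0,
        q1_star=q1_star,
        q0_star=q0_star,
        converged=converged,
    )


def tmle_ate(
    cohort: pd.DataFrame,
    sl_library: list[str] | None = None,
    g_bounds: tuple[float, float] = (0.025, 0.975),
    v: int = 10,
    seed: int = 0,
    treatment_spec: ModelSpec | None = None,
    outcome_spec: ModelSpec | None = None,
    nuisance: NuisanceEstimates | None = None,
    single_epsilon: bool = False,
) -> tuple[ATEEstimate, FluctuationResult]:
    """Targeted maximum likelihood estimation of the risk difference.

    Nuisance functions come from the super learner by default
    (``sl_library`` names over the default three-learner library);
    parametric ``treatment_spec``/``outcome_spec`` or precomputed
    ``nuisance`` values may be supplied instead.  The propensity is
    bounded to ``g_bounds`` before the fluctuation; outcome predictions
    are truncated away from {0,1} before the logit transform.
    """
    a = cohort["a"].to_numpy(dtype=float)
    y = cohort["y"].to_numpy(dtype=float)
    _check_arms(a)
    n = len(cohort)

    if nuisance is not None:
        g, q_obs, q1, q0 = nuisance.g, nuisance.q_obs, nuisance.q1, nuisance.q0
    elif treatment_spec is not None or outcome_spec is not None:
        if treatment_spec is None or outcome_spec is None:
            raise ValueError("supply both parametric specs or neither")
        _, _, g = _fit_propensity(cohort, treatment_spec, ps_tol=None)
        _, q_obs, q1, q0 = _fit_outcome_with_a(cohort, outcome_spec)
    else:
        library = sl_library or ["sl_step", "sl_glm", "sl_glm_interaction"]
        w_cols = [c for c in cohort.columns if c not in ("a", "y")]
        g_sl = sl.superlearner_fit(
            cohort[w_cols], a, sl.make_library(library, tuple(w_cols)),
            v=v, seed=seed,
        )
        g = g_sl.predict(cohort[w_cols])
        q_terms = tuple(["a"] + w_cols)
        q_sl = sl.superlearner_fit(
            cohort[list(q_terms)], y, sl.make_library(library, q_terms),
            v=v, seed=seed + 1,
        )
        q_obs = q_sl.predict(cohort[list(q_terms)])
        q1 = q_sl.predict(cohort[list(q_terms)].assign(a=1.0))
        q0 = q_sl.predict(cohort[list(q_terms)].assign(a=0.0))

    g = bound_propensity(g, *g_bounds)
    q_obs = np.clip(q_obs, QTRUNC, 1 - QTRUNC)
    q1 = np.clip(q1, QTRUNC, 1 - QTRUNC)
    q0 = np.clip(q0, QTRUNC, 1 - QTRUNC)

    if single_epsilon:
        fluct = _fluctuate_single(y, a, g, q_obs, q1, q0)
    else:
        fluct = _fluctuate(y, a, g, q_obs, q1, q0)
    if not fluct.converged:
        raise EstimationError("TMLE fluctuation did not converge")

    q1s, q0s = fluct.q1_star, fluct.q0_star
    psi = float(np.mean(q1s - q0s))
    ic = (
        a / g * (y - q1s)
        - (1 - a) / (1 - g) * (y - q0s)
        + q1s
        - q0s
        - psi
    )
    est = ATEEstimate(
        method="tmle",
        psi=psi,
        se=influence_se(ic),
        diagnostics={
            "ps_summary": overlap_summary(g, a),
            "epsilon": fluct.epsilon,
            "mean_ic": float(np.mean(ic)),
            "g_bounds": g_bounds,
        },
    )
    return est, fluct


def _fluctuate_single(y, a, g, q_obs, q1, q0, max_iter=50, tol=1e-10):
    """One-parameter fluctuation along h = a/g - (1-a)/(1-g)."""
    h = a / g - (1 - a) / (1 - g)
    off = logit(q_obs)
    eps = 0.0
    converged = False
    for _ in range(max_iter):
        mu = expit(off + eps * h)
        grad = float(h @ (y - mu))
        info = float((h * h) @ (mu * (1 - mu)))
        delta = grad / info
        eps += delta
        if abs(delta) < tol:
            converged = True
            break
    q1_star = expit(logit(q1) + eps / g)
    q0_star = expit(logit(q0) - eps / (1 - g))
    return FluctuationResult(
        epsilon=(float(eps), float(eps)),
        h1=a / g,
        h0=-(1 - a) / (1 - g),
        q1_star=q1_star,
        q0_star=q0_star,
        converged=converged,
    )
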