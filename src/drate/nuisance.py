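"""Nuisance models: propensity score g(W) and outcome regression Q(A, W).

Both nuisance functions are logistic regressions over a term language
(main effects ``"w1"``, products ``"w2:w4"``, squares ``"w2^2"``).  The
fitting core is a Newton/IRLS maximum-likelihood routine tuned for the
Monte Carlo loops in this package: it is warm-startable, tolerant of
rank-deficient designs (least-squares Newton steps, rank-aware AIC/BIC)
and reports convergence instead of raising on separation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ModelSpec",
    "FittedModel",
    "NuisanceEstimates",
    "SchemaError",
    "build_design_matrix",
    "parse_term",
    "fit_logistic",
    "predict_logistic",
    "bound_propensity",
    "overlap_summary",
    "expit",
    "logit",
]

# Probabilities are clipped away from {0,1} before any logit transform.
PROB_EPS = 1e-6


class SchemaError(KeyError):
    """A term in a model spec references a column absent from the data."""


def expit(x: np.ndarray) -> np.ndarray:
    """Numerically safe inverse-logit."""
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def logit(p: np.ndarray) -> np.ndarray:
    p = np.clip(np.asarray(p, dtype=float), PROB_EPS, 1.0 - PROB_EPS)
    return np.log(p / (1.0 - p))


@dataclass(frozen=True)
class ModelSpec:
    """A parametric specification for one nuisance regression.

    Parameters
    ----------
    response
        ``"treatment"`` (model for A given W) or ``"outcome"``
        (model for Y given A and W).
    terms
        Ordered term strings over cohort columns: ``"w1"`` (main
        effect), ``"w2:w4"`` (elementwise product), ``"w2^2"``
        (square).  The intercept is implicit and always first.
    include_treatment_main
        For outcome models, whether A enters as a main-effect term
        ahead of the covariate terms.
    """

    response: str
    terms: tuple[str, ...]
    include_treatment_main: bool = True

    def __post_init__(self):
        if self.response not in ("treatment", "outcome"):
            raise ValueError(f"unknown response kind {self.response!r}")
        terms = tuple(self.terms)
        if not terms:
            raise ValueError("term list must be non-empty")
        if len(set(terms)) != len(terms):
            raise ValueError(f"duplicate terms in spec: {terms}")
        object.__setattr__(self, "terms", terms)

    @property
    def all_terms(self) -> tuple[str, ...]:
        """Terms including the forced treatment main effect, if any."""
        if self.response == "outcome" and self.include_treatment_main:
            return ("a",) + tuple(t for t in self.terms if t != "a")
        return tuple(self.terms)


def parse_term(term: str) -> tuple[str, ...]:
    """Decompose a term string into the column names it multiplies.

    ``"w1" -> ("w1",)``; ``"w2:w4" -> ("w2", "w4")``;
    ``"w2^2" -> ("w2", "w2")``; ``"w2^2:w4" -> ("w2", "w2", "w4")``.
    """
    term = term.strip()
    if not term:
        raise ValueError("empty term")
    factors: list[str] = []
    for part in term.split(":"):
        part = part.strip()
        if not part:
            raise ValueError(f"malformed interaction term {term!r}")
        if "^" in part:
            base, _, power = part.partition("^")
            if power != "2" or not base.strip():
                raise ValueError(f"only squared factors supported, got {term!r}")
            factors += [base.strip(), base.strip()]
        else:
            factors.append(part)
    return tuple(factors)


def build_design_matrix(
    cohort: pd.DataFrame, spec: ModelSpec
) -> tuple[np.ndarray, list[str]]:
    """Build the numeric design matrix for ``spec`` on ``cohort``.

    Returns the matrix (intercept column first, then terms in spec
    order) and the column names.  Interaction columns are elementwise
    products; squared columns elementwise squares.
    """
    terms = spec.all_terms
    n = len(cohort)
    cols = [np.ones(n)]
    names = ["(intercept)"]
    for term in terms:
        factors = parse_term(term)
        for c in factors:
            if c not in cohort.columns:
                raise SchemaError(
                    f"term {term!r} references column {c!r} not in cohort "
                    f"(have {list(cohort.columns)})"
                )
        col = np.ones(n)
        for c in factors:
            col = col * cohort[c].to_numpy(dtype=float)
        cols.append(col)
        names.append(term)
    return np.column_stack(cols) if n else np.empty((0, len(names))), names


@dataclass
class FittedModel:
    """A fitted logistic regression with its information criteria."""

    coef: np.ndarray
    log_likelihood: float
    k: int
    aic: float
    bic: float
    converged: bool
    n_iter: int
    cov: np.ndarray | None = None
    column_names: list[str] = field(default_factory=list)
    spec: ModelSpec | None = None

    def predict(self, X: np.ndarray, offset: np.ndarray | None = None) -> np.ndarray:
        eta = X @ self.coef
        if offset is not None:
            eta = eta + offset
        return expit(eta)


def _bernoulli_loglik(y, p, weights):
    p = np.clip(p, PROB_EPS, 1.0 - PROB_EPS)
    ll = y * np.log(p) + (1.0 - y) * np.log(1.0 - p)
    return float(np.sum(weights * ll))


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    *,
    weights: np.ndarray | None = None,
    offset: np.ndarray | None = None,
    start: np.ndarray | None = None,
    max_iter: int = 100,
    tol: float = 1e-8,
    compute_cov: bool = False,
    rank: int | None = None,
    column_names: list[str] | None = None,
    spec: ModelSpec | None = None,
) -> FittedModel:
    """Maximum-likelihood logistic regression by Newton/IRLS.

    Rank-deficient designs are handled by least-squares Newton steps
    (minimum-norm direction) and ``k`` in AIC/BIC is the design rank.
    Separation or non-convergence within ``max_iter`` iterations is
    reported through ``converged=False`` with a warning, never a silent
    failure.  ``weights`` are prior (case) weights; the log-likelihood,
    AIC and BIC are weighted accordingly.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n == 0:
        raise ValueError("cannot fit on an empty design")
    if np.any((y != 0) & (y != 1)):
        raise ValueError("response must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("response is constant; logistic MLE does not exist")
    if n <= 0:
        raise ValueError("empty data")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    off = np.zeros(n) if offset is None else np.asarray(offset, dtype=float)

    # exact collinearity (e.g. the square of a binary column) is
    # resolved by fitting on a pivoted independent subset of columns
    # and reporting zero coefficients for the dropped ones
    XtX = X.T @ X
    if rank is None:
        rank = int(np.linalg.matrix_rank(XtX))
    keep = None
    if rank < p:
        from scipy.linalg import qr as _qr

        _, _, piv = _qr(XtX, pivoting=True)
        keep = np.sort(piv[:rank])
        sub = fit_logistic(
            X[:, keep],
            y,
            weights=weights,
            offset=offset,
            start=None if start is None else np.asarray(start, dtype=float)[keep],
            max_iter=max_iter,
            tol=tol,
            compute_cov=compute_cov,
            rank=rank,
        )
        coef = np.zeros(p)
        coef[keep] = sub.coef
        cov = None
        if compute_cov:
            cov = np.zeros((p, p))
            cov[np.ix_(keep, keep)] = sub.cov
        return FittedModel(
            coef=coef,
            log_likelihood=sub.log_likelihood,
            k=rank,
            aic=sub.aic,
            bic=sub.bic,
            converged=sub.converged,
            n_iter=sub.n_iter,
            cov=cov,
            column_names=column_names or [],
            spec=spec,
        )

    beta = np.zeros(p) if start is None else np.array(start, dtype=float)
    eta = X @ beta + off
    mu = expit(eta)
    ll = _bernoulli_loglik(y, mu, w)

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        s = w * mu * (1.0 - mu)
        grad = X.T @ (w * (y - mu))
        XtWX = (X * s[:, None]).T @ X
        try:
            delta = np.linalg.solve(XtWX, grad)
        except np.linalg.LinAlgError:
            delta, *_ = np.linalg.lstsq(XtWX, grad, rcond=None)
        if not np.all(np.isfinite(delta)):
            delta, *_ = np.linalg.lstsq(XtWX, grad, rcond=None)
        # step-halving keeps the likelihood monotone
        step = 1.0
        for _ in range(25):
            cand = beta + step * delta
            eta_c = X @ cand + off
            mu_c = expit(eta_c)
            ll_c = _bernoulli_loglik(y, mu_c, w)
            if ll_c >= ll - 1e-12:
                break
            step *= 0.5
        moved = float(np.max(np.abs(step * delta))) if p else 0.0
        beta, eta, mu = cand, eta_c, mu_c
        ll_prev, ll = ll, ll_c
        if moved < tol or abs(ll - ll_prev) < tol * (abs(ll_prev) + 1e-3):
            converged = True
            break

    if not converged or np.max(np.abs(beta)) > 40.0:
        if np.max(np.abs(beta)) > 40.0:
            converged = False
        warnings.warn(
            "logistic fit did not converge (possible separation); "
            f"max|coef|={np.max(np.abs(beta)):.2f} after {it} iterations",
            RuntimeWarning,
            stacklevel=2,
        )

    n_eff = float(np.sum(w))
    aic = -2.0 * ll + 2.0 * rank
    bic = -2.0 * ll + rank * float(np.log(n_eff))

    cov = None
    if compute_cov:
        s = w * mu * (1.0 - mu)
        XtWX = (X * s[:, None]).T @ X
        cov = np.linalg.pinv(XtWX)

    return FittedModel(
        coef=beta,
        log_likelihood=ll,
        k=rank,
        aic=aic,
        bic=bic,
        converged=converged,
        n_iter=it,
        cov=cov,
        column_names=column_names or [],
        spec=spec,
    )


def fit_spec(
    cohort: pd.DataFrame,
    response: np.ndarray,
    spec: ModelSpec,
    **kwargs,
) -> FittedModel:
    """Fit a :class:`ModelSpec` on a cohort; convenience over
    :func:`build_design_matrix` + :func:`fit_logistic`."""
    X, names = build_design_matrix(cohort, spec)
    return fit_logistic(X, response, column_names=names, spec=spec, **kwargs)


def predict_logistic(
    fit: FittedModel, cohort: pd.DataFrame, spec: ModelSpec | None = None
) -> np.ndarray:
    spec = spec or fit.spec
    if spec is None:
        raise ValueError("no spec attached to fit; pass one explicitly")
    X, _ = build_design_matrix(cohort, spec)
    return fit.predict(X)


@dataclass
class NuisanceEstimates:
    """Container for fitted nuisance values per subject.

    ``g`` is P(A=1|W); ``q1``/``q0`` are outcome predictions under
    A=1 / A=0; ``q_obs`` is the prediction at the observed arm.
    """

    g: np.ndarray
    q_obs: np.ndarray
    q1: np.ndarray
    q0: np.ndarray
    g_bounds: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self):
        for name in ("g", "q_obs", "q1", "q0"):
            v = getattr(self, name)
            if np.any(v < 0) or np.any(v > 1):
                raise ValueError(f"{name} outside [0,1]")


def bound_propensity(
    g: np.ndarray, lower: float = 0.025, upper: float = 0.975
) -> np.ndarray:
    """Clamp propensity scores to ``[lower, upper]`` elementwise.

    The defaults are the bounds used by the reference TMLE
    implementation.  Order-preserving; identity when called with
    ``(0, 1)``.
    """
    if not (0.0 <= lower < upper <= 1.0):
        raise ValueError(f"require 0 <= lower < upper <= 1, got ({lower}, {upper})")
    return np.clip(np.asarray(g, dtype=float), lower, upper)


_PCTS = (1, 5, 25, 50, 75, 95, 99)


def overlap_summary(
    g: np.ndarray,
    a: np.ndarray,
    *,
    flag_threshold: float = 0.01,
) -> dict:
    """Summarize the propensity-score distribution overall and by arm.

    Near-positivity is flagged when the overall 1st percentile of g
    falls below ``flag_threshold`` (or the minimum does, for tiny
    samples).  An empty arm is flagged, not an error: its summary is
    ``None``.
    """
    g = np.asarray(g, dtype=float)
    a = np.asarray(a)
    if len(g) != len(a):
        raise ValueError("g and a must have equal length")

    def _summ(v: np.ndarray):
        if len(v) == 0:
            return None
        pct = np.percentile(v, _PCTS)
        return {
            "n": int(len(v)),
            "min": float(v.min()),
            **{f"p{q}": float(x) for q, x in zip(_PCTS, pct)},
            "max": float(v.max()),
        }

    overall = _summ(g)
    by_arm = {1: _summ(g[a == 1]), 0: _summ(g[a == 0])}
    flag = bool(overall is not None and overall["p1"] < flag_threshold)
    return {
        "overall": overall,
        "by_arm": by_arm,
        "near_positivity": flag,
        "flag_threshold": flag_threshold,
        "empty_arm": [arm for arm, s in by_arm.items() if s is None],
    }


# ---------------------------------------------------------------------------
# Named spec presets used throughout the benchmark.

#: Correct scenario specs: treatment is main-terms, outcome includes the
#: age-by-comorbidity product that generates the data.
TREATMENT_MAIN_TERMS = ModelSpec("treatment", ("w1", "w2", "w3", "w4"))
TREATMENT_CORRECT_S2 = ModelSpec("treatment", ("w1", "w2", "w3", "w4", "w2:w4"))
OUTCOME_CORRECT = ModelSpec("outcome", ("w1", "w2", "w3", "w4", "w2:w4"))
#: Misspecified presets omit the w2:w4 interaction.
OUTCOME_MAIN_TERMS = ModelSpec("outcome", ("w1", "w2", "w3", "w4"))

SPEC_PRESETS = {
    "treatment_main_terms": TREATMENT_MAIN_TERMS,
    "treatment_correct_s2": TREATMENT_CORRECT_S2,
    "outcome_correct": OUTCOME_CORRECT,
    "outcome_main_terms": OUTCOME_MAIN_TERMS,
}
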