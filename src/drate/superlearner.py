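"""V-fold cross-validated convex ensemble ("super learner").

The default library mirrors the basic library of the reference TMLE
implementation: a bidirectional stepwise-AIC logistic selection, a
main-terms logistic GLM, and a logistic GLM with second-order
polynomials and all pairwise interactions.  Ensemble weights minimize
the cross-validated squared-error risk of the convex combination
(non-negative least squares, renormalized); a log-loss variant is
available behind ``loss="logloss"``.

Fold assignment is stratified on the response by default so that rare
classes appear in every training fold; plain random folds are available
with ``stratify=False``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize, nnls

from .nuisance import FittedModel, expit, fit_logistic

__all__ = [
    "Learner",
    "GLMLearner",
    "GLMInteractionLearner",
    "StepwiseLearner",
    "default_library",
    "make_library",
    "SLFit",
    "make_folds",
    "cv_risk",
    "ensemble_weights",
    "superlearner_fit",
    "superlearner_predict",
]

PRED_TRUNC = 1e-6


def make_folds(
    n: int,
    v: int,
    seed: int,
    strata: np.ndarray | None = None,
) -> np.ndarray:
    """Assign each of ``n`` rows to one of ``v`` folds.

    Fold sizes differ by at most one.  With ``strata`` (e.g. the binary
    response) the assignment balances each stratum across folds, which
    keeps rare outcome classes present in every training split.
    """
    if not 2 <= v <= n:
        raise ValueError(f"need 2 <= v <= n, got v={v}, n={n}")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 29]))
    folds = np.empty(n, dtype=int)
    if strata is None:
        order = rng.permutation(n)
        folds[order] = np.arange(n) % v
    else:
        strata = np.asarray(strata)
        # rotate the fold offset between strata so fold sizes stay
        # balanced overall, not only within stratum
        offset = 0
        for s in np.unique(strata):
            idx = np.flatnonzero(strata == s)
            order = rng.permutation(len(idx))
            folds[idx[order]] = (np.arange(len(idx)) + offset) % v
            offset += len(idx)
    return folds


def _continuous_columns(df: pd.DataFrame, terms: tuple[str, ...]) -> set[str]:
    """Terms worth squaring: more than two distinct observed values."""
    return {t for t in terms if df[t].nunique() > 2}


def _design(df: pd.DataFrame, columns: list[tuple[str, ...]]) -> np.ndarray:
    n = len(df)
    out = np.ones((n, len(columns) + 1))
    for j, factors in enumerate(columns, start=1):
        col = np.ones(n)
        for c in factors:
            col = col * df[c].to_numpy(dtype=float)
        out[:, j] = col
    return out


@dataclass
class _LearnerFit:
    model: FittedModel
    columns: list[tuple[str, ...]]

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        return self.model.predict(_design(df, self.columns))


class Learner:
    """Base class: a named prediction algorithm over cohort columns."""

    name: str = "learner"

    def __init__(self, terms: tuple[str, ...]):
        self.terms = tuple(terms)

    def fit(self, df: pd.DataFrame, y: np.ndarray) -> _LearnerFit:  # pragma: no cover
        raise NotImplementedError


class GLMLearner(Learner):
    """Logistic GLM with all terms as main effects."""

    name = "sl_glm"

    def fit(self, df, y):
        cols = [(t,) for t in self.terms]
        X = _design(df, cols)
        return _LearnerFit(fit_logistic(X, y, rank=X.shape[1]), cols)


class GLMInteractionLearner(Learner):
    """Logistic GLM with main terms, squares of the non-binary terms,
    and all pairwise products."""

    name = "sl_glm_interaction"

    def columns_for(self, df) -> list[tuple[str, ...]]:
        cont = _continuous_columns(df, self.terms)
        cols = [(t,) for t in self.terms]
        cols += [(t, t) for t in self.terms if t in cont]
        cols += [
            (self.terms[i], self.terms[j])
            for i in range(len(self.terms))
            for j in range(i + 1, len(self.terms))
        ]
        return cols

    def fit(self, df, y):
        cols = self.columns_for(df)
        X = _design(df, cols)
        return _LearnerFit(fit_logistic(X, y), cols)


class StepwiseLearner(Learner):
    """Bidirectional stepwise logistic selection by AIC.

    Starts from the intercept-only model with a search scope of all
    main terms plus all pairwise products.  Candidate additions are
    screened by their Rao score statistic and candidate deletions by
    their Wald statistic (both approximate the exact AIC change at cost
    O(n k) per candidate); the best screened move is then verified with
    an exact refit and accepted only if the AIC truly improves.  The
    scan order is the deterministic scope order, so results are
    reproducible.
    """

    name = "sl_step"

    def scope_for(self, df) -> list[tuple[str, ...]]:
        cols = [(t,) for t in self.terms]
        cols += [
            (self.terms[i], self.terms[j])
            for i in range(len(self.terms))
            for j in range(i + 1, len(self.terms))
        ]
        return cols

    def fit(self, df, y):
        scope = self.scope_for(df)
        X = _design(df, scope)  # column 0 = intercept, forced
        y = np.asarray(y, dtype=float)
        m = X.shape[1]
        selected = [0]
        fit = fit_logistic(X[:, selected], y, rank=1)
        max_steps = 2 * m + 2
        for _ in range(max_steps):
            move = self._best_move(X, y, selected, fit)
            if move is None:
                break
            selected, fit = move
        cols = [scope[j - 1] for j in selected if j != 0]
        # re-express as a plain fit over the selected columns
        final = fit_logistic(
            X[:, selected], y, start=fit.coef, rank=fit.k
        )
        return _LearnerFit(final, cols)

    @staticmethod
    def _best_move(X, y, selected, fit):
        n, m = X.shape
        Xs = X[:, selected]
        mu = expit(Xs @ fit.coef)
        w = mu * (1.0 - mu)
        resid = y - mu
        XtWX = (Xs * w[:, None]).T @ Xs
        try:
            XtWX_inv = np.linalg.inv(XtWX)
        except np.linalg.LinAlgError:
            XtWX_inv = np.linalg.pinv(XtWX)

        moves = []  # (predicted delta AIC, kind, column)
        excluded = [j for j in range(m) if j not in selected]
        if excluded:
            Z = X[:, excluded]
            U = Z.T @ resid
            XtWZ = (Xs * w[:, None]).T @ Z
            V = np.einsum("ij,ij->j", Z * w[:, None], Z) - np.einsum(
                "ij,ij->j", XtWZ, XtWX_inv @ XtWZ
            )
            with np.errstate(divide="ignore", invalid="ignore"):
                stat = np.where(V > 1e-10, U**2 / np.maximum(V, 1e-10), 0.0)
            for j, s in zip(excluded, stat):
                moves.append((2.0 - s, "add", j))
        cov_diag = np.diag(XtWX_inv)
        for pos, j in enumerate(selected):
            if j == 0:
                continue
            wald = fit.coef[pos] ** 2 / max(cov_diag[pos], 1e-12)
            moves.append((wald - 2.0, "drop", j))

        moves.sort(key=lambda t: (t[0], t[2]))
        for predicted, kind, j in moves[:2]:
            if predicted >= 0.0:
                break
            if kind == "add":
                new_sel = selected + [j]
                start = np.append(fit.coef, 0.0)
            else:
                new_sel = [s for s in selected if s != j]
                start = np.array(
                    [fit.coef[i] for i, s in enumerate(selected) if s != j]
                )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                new_fit = fit_logistic(
                    X[:, new_sel], y, start=start, rank=len(new_sel)
                )
            if new_fit.aic < fit.aic - 1e-10:
                return new_sel, new_fit
        return None


_LEARNERS = {
    "sl_step": StepwiseLearner,
    "sl_glm": GLMLearner,
    "sl_glm_interaction": GLMInteractionLearner,
}


def make_library(names: list[str], terms: tuple[str, ...]) -> list[Learner]:
    """Instantiate a learner library from configured names."""
    if not names:
        raise ValueError("learner library must be non-empty")
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate learners in library: {names}")
    try:
        return [_LEARNERS[n](terms) for n in names]
    except KeyError as e:  # pragma: no cover
        raise ValueError(f"unknown learner {e.args[0]!r}; have {sorted(_LEARNERS)}")


def default_library(terms: tuple[str, ...]) -> list[Learner]:
    return make_library(["sl_step", "sl_glm", "sl_glm_interaction"], terms)


def cv_risk(
    df: pd.DataFrame,
    y: np.ndarray,
    library: list[Learner],
    folds: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Cross-validated squared-error risk per learner.

    Returns ``(risks, level_one)`` where ``level_one`` is the n-by-L
    matrix of held-out predictions.  A learner that fails on any fold
    receives infinite risk and a column of NaN, with a warning.
    """
    y = np.asarray(y, dtype=float)
    n, L = len(df), len(library)
    level_one = np.full((n, L), np.nan)
    for li, learner in enumerate(library):
        try:
            for f in np.unique(folds):
                hold = folds == f
                fit = learner.fit(df.loc[~hold], y[~hold])
                level_one[hold, li] = fit.predict(df.loc[hold])
        except Exception as e:  # noqa: BLE001 - learner failure is data
            warnings.warn(
                f"learner {learner.name!r} failed in cross-validation "
                f"({e}); assigned infinite risk",
                RuntimeWarning,
                stacklevel=2,
            )
            level_one[:, li] = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        risks = np.nanmean((level_one - y[:, None]) ** 2, axis=0)
    risks = np.where(np.isnan(level_one).any(axis=0), np.inf, risks)
    return risks, level_one


def ensemble_weights(
    level_one: np.ndarray,
    y: np.ndarray,
    cv_risks: np.ndarray | None = None,
    loss: str = "mse",
) -> np.ndarray:
    """Convex weights minimizing the ensemble's level-one risk.

    Squared error uses non-negative least squares, then normalization
    to the simplex.  If the NNLS solution is identically zero the
    weight collapses onto the minimum-CV-risk learner, with a warning.
    """
    y = np.asarray(y, dtype=float)
    Z = np.asarray(level_one, dtype=float)
    L = Z.shape[1]
    ok = ~np.isnan(Z).any(axis=0)
    w = np.zeros(L)
    if loss == "mse":
        if ok.any():
            sol, _ = nnls(Z[:, ok], y)
            w[ok] = sol
    elif loss == "logloss":
        def obj(v):
            p = np.clip(Z[:, ok] @ v, PRED_TRUNC, 1 - PRED_TRUNC)
            return -float(np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))
        k = int(ok.sum())
        res = minimize(
            obj,
            np.full(k, 1.0 / k),
            bounds=[(0.0, 1.0)] * k,
            constraints=[{"type": "eq", "fun": lambda v: v.sum() - 1.0}],
            method="SLSQP",
        )
        w[ok] = np.maximum(res.x, 0.0)
    else:
        raise ValueError(f"unknown loss {loss!r}")
    total = w.sum()
    if total <= 0:
        warnings.warn(
            "degenerate ensemble weights; falling back to the "
            "minimum-CV-risk learner",
            RuntimeWarning,
            stacklevel=2,
        )
        if cv_risks is None:
            cv_risks = np.nanmean((Z - y[:, None]) ** 2, axis=0)
        w = np.zeros(L)
        w[int(np.nanargmin(cv_risks))] = 1.0
        return w
    return w / total


@dataclass
class SLFit:
    """A fitted super learner: CV risks, convex weights, and the
    full-data refits of every learner."""

    learners: list[Learner]
    weights: np.ndarray
    cv_risks: np.ndarray
    folds: np.ndarray
    fits: list

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        n = len(df)
        out = np.zeros(n)
        for w, fit in zip(self.weights, self.fits):
            if w > 0 and fit is not None:
                out += w * fit.predict(df)
        return np.clip(out, PRED_TRUNC, 1.0 - PRED_TRUNC)


def superlearner_fit(
    df: pd.DataFrame,
    y: np.ndarray,
    library: list[Learner],
    v: int = 10,
    seed: int = 0,
    loss: str = "mse",
    stratify: bool = True,
) -> SLFit:
    """Fit the V-fold super learner over ``library``."""
    y = np.asarray(y, dtype=float)
    folds = make_folds(len(df), v, seed, strata=y if stratify else None)
    risks, level_one = cv_risk(df, y, library, folds)
    weights = ensemble_weights(level_one, y, cv_risks=risks, loss=loss)
    fits = []
    for w, learner in zip(weights, library):
        if w > 0:
            fits.append(learner.fit(df, y))
        else:
            fits.append(None)
    return SLFit(
        learners=library, weights=weights, cv_risks=risks, folds=folds, fits=fits
    )


def superlearner_predict(sl: SLFit, df: pd.DataFrame) -> np.ndarray:
    return sl.predict(df)
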