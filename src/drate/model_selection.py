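"""Data-adaptive model selection by AIC/BIC over a nested candidate
ladder ("best fit" selection).

Candidates grow from a single main effect to a fully interacted
order-2 polynomial: each additional main effect, then each squared
term, then each pairwise product, in a fixed documented order.  Every
candidate is fitted by maximum likelihood and the ranking table is
returned alongside the chosen specification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .nuisance import ModelSpec, build_design_matrix, fit_logistic

__all__ = ["CandidateRanking", "SelectionError", "enumerate_candidates", "bfit_select"]


class SelectionError(RuntimeError):
    """No candidate model could be fitted."""


def enumerate_candidates(
    covariates: list[str],
    order: int = 2,
    response: str = "outcome",
) -> list[ModelSpec]:
    """The nested candidate ladder over ``covariates``.

    Order 1 yields the main-effect ladder only; order 2 continues with
    squared terms and then pairwise products, ending at the fully
    interacted order-2 polynomial.  Candidate sizes are strictly
    increasing.  Orders above 2 are not implemented.
    """
    if order not in (1, 2):
        raise NotImplementedError(f"order must be 1 or 2, got {order}")
    if not covariates:
        raise ValueError("need at least one covariate")
    specs = []
    terms: list[str] = []
    for c in covariates:
        terms.append(c)
        specs.append(ModelSpec(response, tuple(terms)))
    if order == 2:
        for c in covariates:
            terms.append(f"{c}^2")
            specs.append(ModelSpec(response, tuple(terms)))
        m = len(covariates)
        for i in range(m):
            for j in range(i + 1, m):
                terms.append(f"{covariates[i]}:{covariates[j]}")
                specs.append(ModelSpec(response, tuple(terms)))
    return specs


@dataclass
class CandidateRanking:
    """Fitted candidates with their information criteria.

    ``chosen`` indexes the candidate minimizing the configured
    criterion; ties break toward fewer parameters, then earlier
    enumeration order.
    """

    candidates: list[ModelSpec]
    table: pd.DataFrame
    chosen: int
    criterion: str

    @property
    def chosen_spec(self) -> ModelSpec:
        return self.candidates[self.chosen]


def bfit_select(
    cohort: pd.DataFrame,
    response: np.ndarray | str,
    candidates: list[ModelSpec],
    criterion: str = "aic",
) -> CandidateRanking:
    """Fit every candidate and rank by AIC/BIC.

    Non-convergent fits are kept in the table but never chosen unless
    nothing converged better; if every candidate fails outright a
    :class:`SelectionError` is raised.
    """
    if criterion not in ("aic", "bic"):
        raise ValueError(f"criterion must be 'aic' or 'bic', got {criterion!r}")
    if not candidates:
        raise ValueError("candidate list must be non-empty")
    y = (
        cohort[response].to_numpy(dtype=float)
        if isinstance(response, str)
        else np.asarray(response, dtype=float)
    )
    rows = []
    for i, spec in enumerate(candidates):
        X, _ = build_design_matrix(cohort, spec)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                fit = fit_logistic(X, y)
            rows.append(
                {
                    "candidate": i,
                    "terms": " + ".join(spec.all_terms),
                    "k": fit.k,
                    "loglik": fit.log_likelihood,
                    "aic": fit.aic,
                    "bic": fit.bic,
                    "converged": fit.converged,
                }
            )
        except Exception as e:  # noqa: BLE001 - candidate failure is data
            rows.append(
                {
                    "candidate": i,
                    "terms": " + ".join(spec.all_terms),
                    "k": np.nan,
                    "loglik": np.nan,
                    "aic": np.inf,
                    "bic": np.inf,
                    "converged": False,
                }
            )
    table = pd.DataFrame(rows)
    if not np.isfinite(table[criterion]).any():
        raise SelectionError("no candidate model could be fitted")
    # rank: criterion, then k, then enumeration order; prefer converged
    ranked = table.sort_values(
        by=["converged", criterion, "k", "candidate"],
        ascending=[False, True, True, True],
        kind="mergesort",
    )
    chosen = int(ranked.iloc[0]["candidate"])
    order = {int(c): pos + 1 for pos, c in enumerate(ranked["candidate"])}
    table["rank"] = table["candidate"].map(order)
    return CandidateRanking(
        candidates=list(candidates), table=table, chosen=chosen, criterion=criterion
    )
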