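"""Conditional logistic regression for 1:1 matched pairs.

The conditional likelihood of a 1:1 matched pair is
``exp(x_case b) / (exp(x_case b) + exp(x_ref b))``, which equals an
intercept-free logistic likelihood evaluated on the within-pair difference
``d = x_case - x_ref`` with outcome fixed at 1. Exposure-concordant pairs
(d = 0 in every column) contribute a constant and are dropped; covariates
that are constant within every pair (exactly matched ones) have d = 0 and
are dropped from the design, which provably leaves the remaining
coefficients unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special

from .cohort import PairIndex
from .factors import FactorScoreMatrix

__all__ = [
    "CLRFit",
    "JointCLRFit",
    "fit_conditional_logit",
    "fit_conditional_logit_joint",
    "matched_auc",
]

_Z975 = 1.959963984540054


@dataclass
class CLRFit:
    factor_id: str
    beta: float
    se: float
    or_value: float
    ci95: tuple[float, float]
    covariates: tuple[str, ...]
    n_informative_pairs: int
    converged: bool
    separation: bool = False
    dropped_covariates: tuple[str, ...] = ()
    n_dropped_pairs: int = 0


@dataclass
class JointCLRFit:
    factor_ids: tuple[str, ...]
    beta: np.ndarray
    se: np.ndarray
    converged: bool


def _newton_clr(D: np.ndarray, tol: float = 1e-8, max_iter: int = 100
                ) -> tuple[np.ndarray, np.ndarray, bool]:
    """Maximize sum log sigmoid(D @ beta); returns (beta, cov, converged)."""
    n, p = D.shape
    beta = np.zeros(p)
    converged = False
    for _ in range(max_iter):
        eta = D @ beta
        mu = special.expit(eta)
        grad = D.T @ (1.0 - mu)
        w = mu * (1.0 - mu)
        hess = (D * w[:, None]).T @ D
        if np.linalg.norm(grad) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
        # step-halving to keep the log-likelihood moving uphill
        ll = np.sum(np.log(special.expit(eta) + 1e-300))
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_new = np.sum(np.log(special.expit(D @ cand) + 1e-300))
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        beta = beta + scale * step
        if np.max(np.abs(beta)) > 30:  # diverging: separation
            break
    mu = special.expit(D @ beta)
    w = mu * (1.0 - mu)
    hess = (D * w[:, None]).T @ D
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
    return beta, cov, converged


def _difference_design(
    scores: FactorScoreMatrix,
    pairs: PairIndex,
    covariates: pd.DataFrame | None,
    columns: Sequence[str],
) -> tuple[np.ndarray, list[str], int]:
    """Within-pair (case - reference) differences for the requested columns.

    Returns the difference matrix, the retained column names (zero-difference
    columns are dropped), and the number of pairs dropped for missing
    covariate values.
    """
    frames = [scores.to_frame().astype(float)]
    if covariates is not None:
        frames.append(covariates.astype(float))
    X = pd.concat(frames, axis=1)
    missing_cols = [c for c in columns if c not in X.columns]
    if missing_cols:
        raise KeyError(f"unknown design columns: {missing_cols}")
    X = X[list(columns)]
    case_ids = [scores.patient_ids[i] for i in pairs.case_rows]
    ref_ids = [scores.patient_ids[i] for i in pairs.ref_rows]
    D = X.reindex(case_ids).to_numpy() - X.reindex(ref_ids).to_numpy()
    ok = ~np.isnan(D).any(axis=1)
    n_dropped = int((~ok).sum())
    D = D[ok]
    keep = [j for j in range(D.shape[1]) if np.any(D[:, j] != 0)]
    names = [columns[j] for j in keep]
    return D[:, keep], names, n_dropped


def fit_conditional_logit(
    scores: FactorScoreMatrix,
    pairs: PairIndex,
    factor_id: str,
    covariates: pd.DataFrame | None = None,
    adjust: Sequence[str] = (),
) -> CLRFit:
    """Fit the 1:1 conditional logistic model for one factor.

    ``covariates`` is a patient-indexed frame supplying the ``adjust``
    columns (for example age, rurality, income). Pairs with a missing
    covariate are dropped and counted. Wald 95% intervals are
    ``exp(beta +- 1.96 se)``; separation (all informative differences on
    one side) is flagged and reported as an infinite or zero OR rather
    than raised.
    """
    columns = [factor_id, *adjust]
    D, names, n_dropped = _difference_design(scores, pairs, covariates, columns)
    dropped = tuple(c for c in columns if c not in names)
    if factor_id not in names:
        raise ValueError(f"no informative pairs for factor {factor_id}")
    informative = D[:, names.index(factor_id)] != 0
    n_informative = int(informative.sum())

    # only exposure-discordant pairs carry information; concordant rows are
    # constants in the likelihood but harmless, keep rows with any signal
    rows = np.any(D != 0, axis=1)
    D = D[rows]

    d_f = D[:, names.index(factor_id)]
    separation = bool(n_informative > 0 and (np.all(d_f >= 0) or np.all(d_f <= 0)))
    if separation:
        sign = 1.0 if np.all(d_f >= 0) else -1.0
        return CLRFit(factor_id=factor_id, beta=sign * np.inf, se=np.nan,
                      or_value=np.inf if sign > 0 else 0.0, ci95=(0.0, np.inf),
                      covariates=tuple(adjust),
                      n_informative_pairs=n_informative, converged=False,
                      separation=True, dropped_covariates=dropped,
                      n_dropped_pairs=n_dropped)

    beta_vec, cov, converged = _newton_clr(D)
    j = names.index(factor_id)
    beta = float(beta_vec[j])
    se = float(np.sqrt(cov[j, j])) if np.isfinite(cov[j, j]) else np.nan

    or_value = float(np.exp(beta))
    with np.errstate(over="ignore"):  # huge se -> infinite upper limit
        ci = (float(np.exp(beta - _Z975 * se)), float(np.exp(beta + _Z975 * se)))
    return CLRFit(factor_id=factor_id, beta=beta, se=se, or_value=or_value,
                  ci95=ci, covariates=tuple(adjust),
                  n_informative_pairs=n_informative, converged=converged,
                  separation=False, dropped_covariates=dropped,
                  n_dropped_pairs=n_dropped)


def fit_conditional_logit_joint(
    scores: FactorScoreMatrix,
    pairs: PairIndex,
    covariates: pd.DataFrame | None = None,
    adjust: Sequence[str] = (),
) -> JointCLRFit:
    """Joint conditional-logistic fit over all factor scores at once."""
    columns = [*scores.factor_ids, *adjust]
    D, names, _ = _difference_design(scores, pairs, covariates, columns)
    if D.shape[1] == 0 or not np.any(D != 0):
        raise ValueError("no informative pairs for a joint fit")
    D = D[np.any(D != 0, axis=1)]
    beta, cov, converged = _newton_clr(D)
    full_beta = np.zeros(len(scores.factor_ids))
    full_se = np.full(len(scores.factor_ids), np.nan)
    for j, name in enumerate(names):
        if name in scores.factor_ids:
            i = scores.factor_ids.index(name)
            full_beta[i] = beta[j]
            full_se[i] = np.sqrt(cov[j, j]) if np.isfinite(cov[j, j]) else np.nan
    return JointCLRFit(factor_ids=tuple(scores.factor_ids), beta=full_beta,
                       se=full_se, converged=converged)


def matched_auc(predictor: Mapping[str, float], pairs: PairIndex,
                patient_ids: Sequence[str] | None = None) -> float:
    """Within-pair concordance: fraction of pairs where the case's linear
    predictor exceeds the reference's, ties counting one half.

    ``pairs`` stores row positions into ``patient_ids`` (defaults to the
    insertion order of the ``predictor`` mapping, which matches the score
    matrix used to build it).
    """
    if len(pairs) == 0:
        raise ValueError("no pairs")
    ids = list(predictor.keys()) if patient_ids is None else list(patient_ids)
    vals = np.array([predictor[p] for p in ids], dtype=float)
    case = vals[pairs.case_rows]
    ref = vals[pairs.ref_rows]
    wins = np.sum(case > ref) + 0.5 * np.sum(case == ref)
    return float(wins / len(pairs))
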