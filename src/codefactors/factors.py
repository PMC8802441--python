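"""Principal-components factor analysis of retained binary codes.

Loadings come from the eigendecomposition of the code-by-code Pearson
correlation matrix: the loading of code ``i`` on factor ``j`` is the
``i``-th entry of eigenvector ``j`` scaled by the square root of its
eigenvalue, so squared loadings in a column sum to the eigenvalue and all
eigenvalues sum to the number of codes. A code joins every factor on which
the absolute loading reaches the cutoff (0.2 by default), and a patient
scores 1 on a factor if they carry any of its member codes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .cohort import CodeMatrix

__all__ = [
    "FactorAssignment",
    "FactorDefinition",
    "FactorModel",
    "FactorScoreMatrix",
    "choose_n_factors",
    "define_factors",
    "fit_pca_factors",
    "score_patients",
]


@dataclass
class FactorModel:
    code_ids: list[str]
    eigenvalues: np.ndarray  # descending
    loadings: np.ndarray  # codes x factors
    cumulative_variance: np.ndarray

    @property
    def n_codes(self) -> int:
        return len(self.code_ids)


@dataclass(frozen=True)
class FactorDefinition:
    factor_id: str
    label: str
    code_ids: frozenset[str]
    cutoff_used: float

    def __post_init__(self) -> None:
        if not self.code_ids:
            raise ValueError("factor definition needs at least one code")


class FactorAssignment(NamedTuple):
    definitions: list[FactorDefinition]
    unassigned: list[str]


@dataclass
class FactorScoreMatrix:
    patient_ids: list[str]
    factor_ids: list[str]
    values: np.ndarray  # binary, patients x factors

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.uint8)
        if self.values.shape != (len(self.patient_ids), len(self.factor_ids)):
            raise ValueError("values shape does not match ids")

    def column(self, factor_id: str) -> np.ndarray:
        return self.values[:, self.factor_ids.index(factor_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.patient_ids,
                            columns=self.factor_ids)


def fit_pca_factors(matrix: CodeMatrix, n_factors: int | None = None,
                    rotation: str | None = None) -> FactorModel:
    """Eigendecompose the code correlation matrix into factor loadings.

    Columns are ordered by descending eigenvalue; each column is signed so
    its largest-magnitude loading is positive. ``n_factors`` trims the
    loading matrix (eigenvalues are always kept in full so variance
    accounting stays exact). ``rotation="varimax"`` rotates the trimmed
    loading columns (identity properties tied to the eigenvalues then no
    longer apply column-wise); the default is the unrotated solution.
    """
    if len(matrix.codes) < 2:
        raise ValueError("need at least two codes for a factor model")
    X = matrix.values.astype(float)
    variances = X.var(axis=0)
    dead = [c for c, v in zip(matrix.codes, variances) if v == 0]
    if dead:
        raise ValueError(f"zero-variance codes cannot be factored: {dead[:10]}")
    corr = np.corrcoef(X, rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]
    loadings = eigvec * np.sqrt(np.clip(eigval, 0.0, None))
    if n_factors is not None:
        loadings = loadings[:, :n_factors]
    if rotation == "varimax":
        loadings = _varimax(loadings)
    elif rotation is not None:
        raise ValueError(f"unknown rotation {rotation!r}")
    for j in range(loadings.shape[1]):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] = -loadings[:, j]
    cumvar = np.cumsum(eigval) / len(matrix.codes)
    return FactorModel(code_ids=list(matrix.codes), eigenvalues=eigval,
                       loadings=loadings, cumulative_variance=cumvar)


def _varimax(loadings: np.ndarray, tol: float = 1e-8, max_iter: int = 200) -> np.ndarray:
    """Orthogonal varimax rotation (Kaiser, unnormalized)."""
    p, k = loadings.shape
    if k < 2:
        return loadings
    R = np.eye(k)
    variance = 0.0
    for _ in range(max_iter):
        L = loadings @ R
        u, s, vt = np.linalg.svd(
            loadings.T @ (L**3 - L @ np.diag((L**2).sum(axis=0)) / p))
        R = u @ vt
        new_variance = s.sum()
        if new_variance < variance * (1 + tol):
            break
        variance = new_variance
    return loadings @ R


def _kaiser(eigenvalues: np.ndarray) -> int:
    return int(np.sum(eigenvalues > 1.0))


def _scree_breakpoint(eigenvalues: np.ndarray) -> int:
    # elbow = position of the largest second difference of the scree curve
    e = np.asarray(eigenvalues, dtype=float)
    if e.size < 3:
        return 1
    second = e[:-2] - 2.0 * e[1:-1] + e[2:]
    return int(np.argmax(second)) + 1


def _cumulative_variance(model: FactorModel, target: float) -> int:
    reached = np.flatnonzero(model.cumulative_variance >= target)
    return int(reached[0]) + 1 if reached.size else model.n_codes


def choose_n_factors(
    model: FactorModel,
    criteria: Sequence[str] = ("kaiser", "scree_breakpoint"),
    params: dict | None = None,
) -> tuple[int, dict[str, int]]:
    """Combine factor-count criteria into a single choice.

    Supported criteria: ``kaiser`` (eigenvalues > 1), ``scree_breakpoint``
    (largest second difference of the scree curve), ``cumulative_variance``
    (smallest count reaching ``params['variance_target']``, default 0.8),
    and ``auc_loop`` (count of leading factors maximizing matched
    concordance of a conditional-logistic fit; needs ``params['matrix']``,
    ``params['pairs']`` and optionally ``params['cutoff']``/``max_k``/
    ``min_gain``). In-sample concordance never stops creeping upward as
    spurious factors enter, so the loop only moves to a larger count when
    the AUC improves by at least ``min_gain`` (default 0.01).
    The final answer is the median of the invoked criteria, rounded up.
    """
    params = params or {}
    report: dict[str, int] = {}
    for criterion in criteria:
        if criterion == "kaiser":
            report[criterion] = _kaiser(model.eigenvalues)
        elif criterion == "scree_breakpoint":
            report[criterion] = _scree_breakpoint(model.eigenvalues)
        elif criterion == "cumulative_variance":
            report[criterion] = _cumulative_variance(
                model, params.get("variance_target", 0.8))
        elif criterion == "auc_loop":
            if "matrix" not in params or "pairs" not in params:
                raise ValueError("auc_loop requires pair data "
                                 "(params['matrix'] and params['pairs'])")
            report[criterion] = _auc_loop(model, params)
        else:
            raise ValueError(f"unknown criterion {criterion!r}")
    if not report:
        raise ValueError("no criteria requested")
    chosen = int(math.ceil(float(np.median(list(report.values())))))
    return max(1, chosen), report


def _auc_loop(model: FactorModel, params: dict) -> int:
    from .association import fit_conditional_logit_joint, matched_auc

    matrix: CodeMatrix = params["matrix"]
    pairs = params["pairs"]
    cutoff = params.get("cutoff", 0.2)
    max_k = params.get("max_k", min(10, model.loadings.shape[1]))
    min_gain = params.get("min_gain", 0.01)
    best_k, best_auc = 1, -np.inf
    for k in range(1, max_k + 1):
        definitions, _ = define_factors(model, k, cutoff=cutoff, warn_empty=False)
        if not definitions:
            continue
        scores = score_patients(matrix, definitions)
        try:
            fit = fit_conditional_logit_joint(scores, pairs)
        except ValueError:
            continue
        predictor = scores.values.astype(float) @ fit.beta
        auc = matched_auc(dict(zip(scores.patient_ids, predictor)), pairs)
        if auc > best_auc + min_gain:
            best_k, best_auc = k, auc
    return best_k


def define_factors(
    model: FactorModel,
    n_factors: int,
    cutoff: float = 0.2,
    labels: Sequence[str] | None = None,
    warn_empty: bool = True,
) -> FactorAssignment:
    """Turn the first ``n_factors`` loading columns into code-set definitions.

    A code joins every factor where its absolute loading reaches the
    cutoff; multi-membership is allowed. Factors with no qualifying code
    are dropped (with a warning); codes qualifying nowhere are returned in
    the ``unassigned`` list.
    """
    if not 0 < cutoff < 1:
        raise ValueError("cutoff must lie in (0, 1)")
    if n_factors > model.loadings.shape[1]:
        raise ValueError("n_factors exceeds available loading columns")
    definitions: list[FactorDefinition] = []
    assigned: set[str] = set()
    for j in range(n_factors):
        col = model.loadings[:, j]
        members = [c for c, w in zip(model.code_ids, col) if abs(w) >= cutoff]
        if not members:
            if warn_empty:
                warnings.warn(f"factor {j + 1} has no codes at cutoff {cutoff}",
                              stacklevel=2)
            continue
        assigned.update(members)
        if labels is not None and j < len(labels):
            label = labels[j]
        else:
            top = sorted(members, key=lambda c: -abs(col[model.code_ids.index(c)]))
            label = "+".join(top[:3])
        definitions.append(FactorDefinition(
            factor_id=f"F{j + 1}", label=label,
            code_ids=frozenset(members), cutoff_used=cutoff))
    unassigned = [c for c in model.code_ids if c not in assigned]
    return FactorAssignment(definitions=definitions, unassigned=unassigned)


def score_patients(
    matrix: CodeMatrix,
    definitions: Sequence[FactorDefinition],
) -> FactorScoreMatrix:
    """Any-of binary scoring: 1 iff the patient carries a member code."""
    unknown = sorted(set().union(*(d.code_ids for d in definitions))
                     - set(matrix.codes))
    if unknown:
        raise ValueError(f"definitions reference unknown codes: {unknown[:10]}")
    cols = []
    for d in definitions:
        idx = [matrix.codes.index(c) for c in sorted(d.code_ids)]
        cols.append((matrix.values[:, idx].sum(axis=1) > 0).astype(np.uint8))
    values = np.column_stack(cols) if cols else np.zeros((len(matrix.patient_ids), 0), np.uint8)
    return FactorScoreMatrix(patient_ids=list(matrix.patient_ids),
                             factor_ids=[d.factor_id for d in definitions],
                             values=values)
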