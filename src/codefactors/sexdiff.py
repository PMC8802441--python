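"""Per-sex factor correlation matrices and Fisher-z hypothesis machinery.

Correlations between binary factor scores are plain Pearson correlations
(the phi coefficient). Each correlation ``r`` is transformed to
``r' = arctanh(r) = 0.5 * ln((1 + r) / (1 - r))`` whose sampling variance
is ``1 / (n - 3)``. Within-sex nullity and the female-minus-male
difference are tested with normal z statistics

    z = r' * sqrt(n - 3)
    z = (r'_F - r'_M) / sqrt(1/(n_F - 3) + 1/(n_M - 3))

and each of the three hypothesis families (female, male, difference) is
FDR-masked separately with the BY procedure: non-significant entries are
zeroed while significant entries keep their raw value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .factors import FactorScoreMatrix
from .screening import by_adjust

__all__ = [
    "CorrelationMatrix",
    "FisherTest",
    "MaskedCorrelations",
    "SexDifferenceTest",
    "fdr_mask",
    "fisher_transform",
    "phi_matrix",
    "z_difference",
    "z_single",
]

_CLAMP = 1.0 - 1e-12


@dataclass
class CorrelationMatrix:
    factor_ids: list[str]
    values: np.ndarray
    sex: str
    n: int
    excluded: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        k = len(self.factor_ids)
        if self.values.shape != (k, k):
            raise ValueError("correlation matrix shape mismatch")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if self.n < 4:
            raise ValueError("need n >= 4 for a defined Fisher variance")

    def value(self, f: str, g: str) -> float:
        i, j = self.factor_ids.index(f), self.factor_ids.index(g)
        return float(self.values[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.factor_ids,
                            columns=self.factor_ids)


@dataclass(frozen=True)
class FisherTest:
    pair: tuple[str, str]
    r: float
    r_prime: float
    n: int
    z: float
    p: float
    clamped: bool = False


@dataclass(frozen=True)
class SexDifferenceTest:
    pair: tuple[str, str]
    r_F: float
    r_M: float
    r_prime_F: float
    r_prime_M: float
    n_F: int
    n_M: int
    z: float
    p: float


def phi_matrix(scores: FactorScoreMatrix, sex: str,
               patient_mask: np.ndarray | None = None) -> CorrelationMatrix:
    """Pearson (phi) correlation matrix of binary factor scores.

    Zero-variance factors are excluded with a warning rather than raised,
    so degenerate synthetic fixtures stay usable.
    """
    X = scores.values.astype(float)
    if patient_mask is not None:
        X = X[patient_mask]
    n = X.shape[0]
    if n < 4:
        raise ValueError("need at least 4 patients")
    keep = X.var(axis=0) > 0
    excluded = tuple(f for f, k in zip(scores.factor_ids, keep) if not k)
    if excluded:
        warnings.warn(f"zero-variance factors excluded: {excluded}", stacklevel=2)
    X = X[:, keep]
    ids = [f for f, k in zip(scores.factor_ids, keep) if k]
    corr = np.corrcoef(X, rowvar=False)
    corr = np.atleast_2d(corr)
    np.fill_diagonal(corr, 1.0)
    corr = (corr + corr.T) / 2.0
    return CorrelationMatrix(factor_ids=ids, values=corr, sex=sex, n=n,
                             excluded=excluded)


def fisher_transform(r):
    """``0.5 * ln((1 + r) / (1 - r))``; errors on |r| >= 1."""
    arr = np.asarray(r, dtype=float)
    if np.any(np.abs(arr) >= 1.0):
        raise ValueError("|r| >= 1 has an infinite Fisher transform")
    out = np.arctanh(arr)
    return float(out) if np.isscalar(r) or arr.ndim == 0 else out


def _clamp(r: float) -> tuple[float, bool]:
    if abs(r) >= 1.0:
        return float(np.sign(r)) * _CLAMP, True
    return float(r), False


def z_single(r: float, n: int, pair: tuple[str, str] = ("", "")) -> FisherTest:
    """Test H0: r' = 0 with z = r' * sqrt(n - 3)."""
    if n < 4:
        raise ValueError("need n >= 4")
    rc, clamped = _clamp(r)
    r_prime = fisher_transform(rc)
    z = r_prime * np.sqrt(n - 3)
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return FisherTest(pair=pair, r=float(r), r_prime=float(r_prime), n=n,
                      z=float(z), p=p, clamped=clamped)


def z_difference(r_F: float, n_F: int, r_M: float, n_M: int,
                 pair: tuple[str, str] = ("", "")) -> SexDifferenceTest:
    """Test H0: r'_F - r'_M = 0 between two independent samples."""
    if n_F < 4 or n_M < 4:
        raise ValueError("need n >= 4 in each group")
    rf, _ = _clamp(r_F)
    rm, _ = _clamp(r_M)
    rpF = fisher_transform(rf)
    rpM = fisher_transform(rm)
    se = np.sqrt(1.0 / (n_F - 3) + 1.0 / (n_M - 3))
    z = (rpF - rpM) / se
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return SexDifferenceTest(pair=pair, r_F=float(r_F), r_M=float(r_M),
                             r_prime_F=float(rpF), r_prime_M=float(rpM),
                             n_F=n_F, n_M=n_M, z=float(z), p=p)


@dataclass
class MaskedCorrelations:
    """FDR-masked female, male, and female-minus-male matrices."""

    factor_ids: list[str]
    female: np.ndarray
    male: np.ndarray
    difference: np.ndarray
    tests_female: list[FisherTest]
    tests_male: list[FisherTest]
    tests_difference: list[SexDifferenceTest]

    def frames(self) -> dict[str, pd.DataFrame]:
        ids = self.factor_ids
        return {name: pd.DataFrame(values, index=ids, columns=ids)
                for name, values in (("F", self.female), ("M", self.male),
                                     ("F-M", self.difference))}


def _pair_list(ids: Sequence[str]) -> list[tuple[str, str]]:
    return list(combinations(ids, 2))


def fdr_mask(corr_F: CorrelationMatrix, corr_M: CorrelationMatrix,
             q: float = 0.05, joint: bool = False) -> MaskedCorrelations:
    """Run the three hypothesis families over all factor pairs and zero the
    non-significant entries of each matrix.

    The female and male families test each within-sex correlation against
    zero; the difference family tests the equality of the Fisher-transformed
    correlations between sexes. Each family is BY-corrected separately at
    level ``q`` by default (``joint=True`` pools all three families into a
    single correction). Diagonals are fixed at 1 (difference: 0).
    """
    shared = [f for f in corr_F.factor_ids if f in set(corr_M.factor_ids)]
    pairs = _pair_list(shared)
    if len(pairs) != len(set(pairs)):
        raise ValueError("duplicate factor pairs")
    if not pairs:
        raise ValueError("need at least two shared factors")

    tests_F = [z_single(corr_F.value(f, g), corr_F.n, pair=(f, g)) for f, g in pairs]
    tests_M = [z_single(corr_M.value(f, g), corr_M.n, pair=(f, g)) for f, g in pairs]
    tests_D = [z_difference(corr_F.value(f, g), corr_F.n,
                            corr_M.value(f, g), corr_M.n, pair=(f, g))
               for f, g in pairs]

    if joint:
        pooled = by_adjust([t.p for t in tests_F] + [t.p for t in tests_M]
                           + [t.p for t in tests_D], q=q).rejected_mask()
        n = len(pairs)
        sig_F, sig_M, sig_D = pooled[:n], pooled[n:2 * n], pooled[2 * n:]
    else:
        sig_F = by_adjust([t.p for t in tests_F], q=q).rejected_mask()
        sig_M = by_adjust([t.p for t in tests_M], q=q).rejected_mask()
        sig_D = by_adjust([t.p for t in tests_D], q=q).rejected_mask()

    k = len(shared)
    female = np.eye(k)
    male = np.eye(k)
    difference = np.zeros((k, k))
    pos = {f: i for i, f in enumerate(shared)}
    for idx, (f, g) in enumerate(pairs):
        i, j = pos[f], pos[g]
        if sig_F[idx]:
            female[i, j] = female[j, i] = tests_F[idx].r
        if sig_M[idx]:
            male[i, j] = male[j, i] = tests_M[idx].r
        if sig_D[idx]:
            d = tests_D[idx].r_F - tests_D[idx].r_M
            difference[i, j] = difference[j, i] = d
    return MaskedCorrelations(factor_ids=shared, female=female, male=male,
                              difference=difference, tests_female=tests_F,
                              tests_male=tests_M, tests_difference=tests_D)


def fdr_mask_rect(values_F: pd.DataFrame, n_F: int,
                  values_M: pd.DataFrame, n_M: int,
                  q: float = 0.05) -> dict[str, pd.DataFrame]:
    """FDR masking for rectangular association matrices (factor x cause).

    Every cell is one hypothesis; the three families (F, M, F-M) are each
    BY-corrected separately, mirroring the square-matrix variant.
    """
    if list(values_F.index) != list(values_M.index) or \
            list(values_F.columns) != list(values_M.columns):
        raise ValueError("female and male matrices must share row/column ids")
    rows, cols = values_F.index, values_F.columns
    cells = [(i, j) for i in range(len(rows)) for j in range(len(cols))]
    tests_F = [z_single(values_F.iat[i, j], n_F) for i, j in cells]
    tests_M = [z_single(values_M.iat[i, j], n_M) for i, j in cells]
    tests_D = [z_difference(values_F.iat[i, j], n_F, values_M.iat[i, j], n_M)
               for i, j in cells]
    out = {}
    for name, tests, sig in (
        ("F", tests_F, by_adjust([t.p for t in tests_F], q=q).rejected_mask()),
        ("M", tests_M, by_adjust([t.p for t in tests_M], q=q).rejected_mask()),
        ("F-M", tests_D, by_adjust([t.p for t in tests_D], q=q).rejected_mask()),
    ):
        mat = np.zeros((len(rows), len(cols)))
        for idx, (i, j) in enumerate(cells):
            if sig[idx]:
                t = tests[idx]
                mat[i, j] = (t.r_F - t.r_M) if name == "F-M" else t.r
        out[name] = pd.DataFrame(mat, index=rows, columns=cols)
    return out
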