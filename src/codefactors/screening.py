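"""Matched screening of binary codes: McNemar tests on discordant pairs,
Benjamini-Yekutieli FDR control, and dual-dataset retention.

For a 1:1 matched design only discordant pairs are informative: ``b`` pairs
where the case carries the code and the reference does not, ``c`` pairs the
other way round. The matched odds ratio is ``b / c`` and the test is either
an exact two-sided binomial test of ``b`` against Binomial(b + c, 1/2) or
the one-degree-of-freedom chi-square ``(b - c)^2 / (b + c)``.

The BY step-up procedure rejects the ``k`` smallest of ``m`` sorted
p-values, where ``k`` is the largest rank ``i`` with
``p_(i) <= i * q / (m * H_m)`` and ``H_m = sum_{j=1}^{m} 1/j`` is the
harmonic constant that makes the procedure valid under arbitrary
dependence between tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CodeMatrix, PairIndex

__all__ = [
    "BYOutcome",
    "DiscordantCounts",
    "McNemarResult",
    "ScreenReport",
    "by_adjust",
    "discordant_counts",
    "discordant_table",
    "matched_odds_ratio",
    "mcnemar_test",
    "screen_codes",
]


@dataclass(frozen=True)
class DiscordantCounts:
    code_id: str
    b: int  # case has the code, reference does not
    c: int  # reference has the code, case does not
    n_pairs: int

    def __post_init__(self) -> None:
        if self.b < 0 or self.c < 0 or self.b + self.c > self.n_pairs:
            raise ValueError("invalid discordant counts")


@dataclass(frozen=True)
class McNemarResult:
    code_id: str
    method: str  # "exact" | "chi_square"
    p_value: float
    matched_or: float  # b/c; inf when c == 0 < b; nan when b == c == 0
    statistic: float | None = None
    b: int = 0
    c: int = 0


def discordant_table(matrix: CodeMatrix, pairs: PairIndex) -> pd.DataFrame:
    """Vectorized b/c counts for every code column at once."""
    case = matrix.values[pairs.case_rows].astype(np.int64)
    ref = matrix.values[pairs.ref_rows].astype(np.int64)
    b = ((case == 1) & (ref == 0)).sum(axis=0)
    c = ((case == 0) & (ref == 1)).sum(axis=0)
    return pd.DataFrame({"code": matrix.codes, "b": b, "c": c,
                         "n_pairs": len(pairs)})


def discordant_counts(matrix: CodeMatrix, pairs: PairIndex, code_id: str) -> DiscordantCounts:
    if not matrix.has_code(code_id):
        raise KeyError(f"code {code_id!r} absent from matrix")
    col = matrix.column(code_id)
    case = col[pairs.case_rows]
    ref = col[pairs.ref_rows]
    b = int(np.sum((case == 1) & (ref == 0)))
    c = int(np.sum((case == 0) & (ref == 1)))
    return DiscordantCounts(code_id=code_id, b=b, c=c, n_pairs=len(pairs))


def _mcnemar_p(b: int, c: int, exact_threshold: int,
               continuity_correction: bool = False) -> tuple[str, float, float | None]:
    n = b + c
    if n == 0:
        return "exact", 1.0, None
    if n < exact_threshold:
        p = min(1.0, 2.0 * float(stats.binom.cdf(min(b, c), n, 0.5)))
        return "exact", p, None
    diff = max(0.0, abs(b - c) - 1.0) if continuity_correction else abs(b - c)
    statistic = diff**2 / n
    return "chi_square", float(stats.chi2.sf(statistic, df=1)), float(statistic)


def mcnemar_test(counts: DiscordantCounts, exact_threshold: int = 25,
                 continuity_correction: bool = False) -> McNemarResult:
    """Matched McNemar test on a pair of discordant counts.

    Uses the exact two-sided binomial test when ``b + c < exact_threshold``,
    the chi-square approximation otherwise (Edwards continuity correction
    optional, off by default); ``b + c == 0`` yields p = 1 by convention.
    """
    method, p, statistic = _mcnemar_p(counts.b, counts.c, exact_threshold,
                                      continuity_correction)
    return McNemarResult(code_id=counts.code_id, method=method, p_value=p,
                         matched_or=matched_odds_ratio(counts),
                         statistic=statistic, b=counts.b, c=counts.c)


def matched_odds_ratio(counts: DiscordantCounts) -> float:
    """Discordant-pair odds ratio b/c.

    ``c == 0 < b`` maps to +inf (passes an OR > 1 filter); ``b == c == 0``
    maps to NaN (undefined, fails the filter).
    """
    if counts.b == 0 and counts.c == 0:
        return math.nan
    if counts.c == 0:
        return math.inf
    return counts.b / counts.c


@dataclass
class BYOutcome:
    m: int
    q: float
    sorted_p: np.ndarray
    thresholds: np.ndarray
    k: int
    rejected: list[str]  # code ids (or stringified indices) of rejected tests
    order: np.ndarray = field(repr=False, default=None)

    def rejected_mask(self) -> np.ndarray:
        """Boolean mask aligned with the *input* order of by_adjust."""
        mask = np.zeros(self.m, dtype=bool)
        if self.k > 0:
            mask[self.order[: self.k]] = True
        return mask


def by_adjust(
    p_values: Sequence[float],
    q: float = 0.05,
    ids: Sequence[str] | None = None,
) -> BYOutcome:
    """Benjamini-Yekutieli step-up procedure at FDR level ``q``."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("by_adjust requires at least one p-value")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    harmonic = np.sum(1.0 / np.arange(1, m + 1))
    thresholds = np.arange(1, m + 1) * q / (m * harmonic)
    passing = np.flatnonzero(sorted_p <= thresholds)
    k = int(passing[-1] + 1) if passing.size else 0
    labels = list(ids) if ids is not None else [str(i) for i in range(m)]
    rejected = [labels[i] for i in order[:k]]
    return BYOutcome(m=m, q=q, sorted_p=sorted_p, thresholds=thresholds,
                     k=k, rejected=rejected, order=order)


@dataclass
class ScreenReport:
    """Outcome of the two-dataset screening stage."""

    datasets: dict[str, pd.DataFrame]  # per-dataset code-level table
    by_outcomes: dict[str, BYOutcome]
    retained: list[str]
    audit: dict[str, dict[str, int]]

    def table(self, dataset: str) -> pd.DataFrame:
        return self.datasets[dataset]


def _screen_one(
    matrix: CodeMatrix,
    pairs: PairIndex,
    q: float,
    exact_threshold: int,
) -> tuple[pd.DataFrame, BYOutcome, dict[str, int]]:
    tab = discordant_table(matrix, pairs)
    present = matrix.values.sum(axis=0) > 0
    skipped = int((~present).sum())
    tab = tab.loc[present].reset_index(drop=True)

    methods, ps, stats_ = [], [], []
    for b, c in zip(tab["b"], tab["c"]):
        method, p, st = _mcnemar_p(int(b), int(c), exact_threshold)
        methods.append(method)
        ps.append(p)
        stats_.append(st)
    tab["method"] = methods
    tab["p_value"] = ps
    tab["statistic"] = stats_
    with np.errstate(divide="ignore", invalid="ignore"):
        tab["matched_or"] = np.where(
            (tab["b"] == 0) & (tab["c"] == 0), np.nan,
            np.where(tab["c"] == 0, np.inf, tab["b"] / tab["c"]))

    outcome = by_adjust(tab["p_value"].to_numpy(), q=q, ids=tab["code"])
    tab["by_rejected"] = outcome.rejected_mask()
    tab["or_gt_one"] = tab["matched_or"] > 1
    tab["selected"] = tab["by_rejected"] & tab["or_gt_one"]
    audit = {
        "codes_total": len(matrix.codes),
        "codes_skipped_absent": skipped,
        "codes_tested": int(len(tab)),
        "by_rejected": int(tab["by_rejected"].sum()),
        "or_filtered": int(tab["selected"].sum()),
    }
    return tab, outcome, audit


def screen_codes(
    train_matrix: CodeMatrix,
    validation_matrix: CodeMatrix,
    train_pairs: PairIndex,
    validation_pairs: PairIndex,
    q: float = 0.05,
    exact_threshold: int = 25,
) -> ScreenReport:
    """Screen every code in both datasets and retain the intersection.

    Per dataset: McNemar test per code, BY correction at level ``q``, then
    an OR > 1 filter. A code is retained only if it survives all three in
    both the training and validation datasets.
    """
    diff = set(train_matrix.codes) ^ set(validation_matrix.codes)
    if diff:
        raise ValueError(f"code universes differ: {sorted(diff)[:20]}")

    train_tab, train_by, train_audit = _screen_one(
        train_matrix, train_pairs, q, exact_threshold)
    val_tab, val_by, val_audit = _screen_one(
        validation_matrix, validation_pairs, q, exact_threshold)

    selected_train = set(train_tab.loc[train_tab["selected"], "code"])
    selected_val = set(val_tab.loc[val_tab["selected"], "code"])
    retained = sorted(selected_train & selected_val)

    train_tab["retained"] = train_tab["code"].isin(retained)
    val_tab["retained"] = val_tab["code"].isin(retained)
    audit = {"training": train_audit, "validation": val_audit,
             "combined": {"retained": len(retained)}}
    return ScreenReport(
        datasets={"training": train_tab, "validation": val_tab},
        by_outcomes={"training": train_by, "validation": val_by},
        retained=retained,
        audit=audit,
    )
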