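"""Ward-linkage clustering on correlation distance, external-cause and
severity association matrices, and heatmap / word-cloud exports.

Ward linkage here follows the convention of applying the Lance-Williams
minimum-variance recurrence directly to the supplied dissimilarities
(the ``ward.D`` convention), which is the common practice with
correlation-based distances. Merge heights under this convention equal
twice the increase in the generalized within-cluster dispersion
``E(C) = (1/|C|) * sum_{i<j in C} d(i, j)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .association import CLRFit
from .cohort import CodeMatrix, EventWindow, normalize_code
from .factors import FactorScoreMatrix
from .sexdiff import CorrelationMatrix

__all__ = [
    "CauseLookup",
    "HeatmapExport",
    "LinkageTree",
    "build_cause_profiles",
    "cause_severity_matrix",
    "correlation_distance",
    "cut_tree",
    "default_cause_lookup",
    "export_heatmap",
    "ward_linkage",
    "wordcloud_weights",
]


def correlation_distance(corr: CorrelationMatrix | np.ndarray,
                         kind: str = "one_minus_r") -> np.ndarray:
    """Correlation-based distance: ``1 - r`` by default, or the chordal
    variant ``sqrt(2 * (1 - r))``; zero diagonal, symmetric."""
    values = corr.values if isinstance(corr, CorrelationMatrix) else np.asarray(corr, float)
    if kind == "one_minus_r":
        d = 1.0 - values
    elif kind == "chordal":
        d = np.sqrt(np.clip(2.0 * (1.0 - values), 0.0, None))
    else:
        raise ValueError(f"unknown distance kind {kind!r}")
    np.fill_diagonal(d, 0.0)
    return d


@dataclass
class LinkageTree:
    """Sequence of agglomerative merges plus the dendrogram leaf order.

    Merge steps use the scipy id convention: original items are
    ``0..n-1`` and the cluster created by step ``t`` has id ``n + t``.
    """

    n_items: int
    merges: list[tuple[int, int, float, int]]  # (a, b, height, new size)
    leaf_order: list[int]

    def to_scipy(self) -> np.ndarray:
        return np.array([[a, b, h, s] for a, b, h, s in self.merges], dtype=float)

    @property
    def heights(self) -> np.ndarray:
        return np.array([h for _, _, h, _ in self.merges])


def ward_linkage(distance: np.ndarray) -> LinkageTree:
    """Agglomerative Ward clustering by the Lance-Williams recurrence.

    Ties break deterministically on the smallest (a, b) cluster-id pair.
    """
    D = np.asarray(distance, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    n = D.shape[0]
    if n < 2:
        raise ValueError("need at least two items")

    dist: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(D[i, j])
    size = {i: 1 for i in range(n)}
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    active = set(range(n))
    merges: list[tuple[int, int, float, int]] = []

    def d_of(a: int, b: int) -> float:
        return dist[(a, b) if a < b else (b, a)]

    next_id = n
    for _ in range(n - 1):
        best = None
        for a in sorted(active):
            for b in sorted(active):
                if b <= a:
                    continue
                d = d_of(a, b)
                if best is None or d < best[0] - 1e-15:
                    best = (d, a, b)
        d_ab, a, b = best
        new = next_id
        next_id += 1
        na, nb = size[a], size[b]
        for k in sorted(active - {a, b}):
            nk = size[k]
            d_new = ((na + nk) * d_of(a, k) + (nb + nk) * d_of(b, k)
                     - nk * d_ab) / (na + nb + nk)
            dist[(min(k, new), max(k, new))] = d_new
        active -= {a, b}
        active.add(new)
        size[new] = na + nb
        members[new] = members[a] + members[b]
        merges.append((a, b, d_ab, na + nb))

    def _order(node: int) -> list[int]:
        if node < n:
            return [node]
        a, b, _, _ = merges[node - n]
        return _order(a) + _order(b)

    return LinkageTree(n_items=n, merges=merges, leaf_order=_order(next_id - 1))


def cut_tree(tree: LinkageTree, k: int) -> np.ndarray:
    """Labels (0..k-1) from cutting the tree into ``k`` clusters."""
    if not 1 <= k <= tree.n_items:
        raise ValueError("k out of range")
    parent = list(range(tree.n_items + len(tree.merges)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for t, (a, b, _, _) in enumerate(tree.merges[: tree.n_items - k]):
        new = tree.n_items + t
        parent[find(a)] = new
        parent[find(b)] = new
    roots: dict[int, int] = {}
    labels = np.empty(tree.n_items, dtype=int)
    for i in range(tree.n_items):
        r = find(i)
        labels[i] = roots.setdefault(r, len(roots))
    return labels


# --- external-cause profiles -------------------------------------------------

_EXTERNAL_CHAPTERS = ("V", "W", "X", "Y")


@dataclass
class CauseLookup:
    """Three-character code ranges per external-cause flag (inclusive)."""

    ranges: dict[str, list[tuple[str, str]]]

    def flags_for(self, code: str) -> set[str]:
        code = code[:3].upper()
        hits = {flag for flag, spans in self.ranges.items()
                if any(lo <= code <= hi for lo, hi in spans)}
        return hits


def default_cause_lookup() -> CauseLookup:
    # illustrative mechanical/intent ranges; editable, not authoritative
    return CauseLookup(ranges={
        "falls": [("W00", "W19")],
        "struck_by_against": [("W20", "W22"), ("W50", "W52")],
        "mvc": [("V02", "V79")],
        "assault": [("X85", "X99"), ("Y00", "Y09")],
    })


def build_cause_profiles(
    matrix: CodeMatrix,
    patients: pd.DataFrame,
    lookup: CauseLookup | None = None,
    sports_codes: Sequence[str] = (),
) -> pd.DataFrame:
    """Per-patient external-cause flags plus severity and covariates.

    A flag is set iff the patient's binarized event window carries any code
    in the flag's ranges; flags are not mutually exclusive. External-cause
    codes matching no flag set ``other``. Severity is taken from the
    patient table's ``severity`` column when present (else "unspecified").
    """
    lookup = lookup or default_cause_lookup()
    sports = {normalize_code(c)[:3] for c in sports_codes}
    flag_names = list(lookup.ranges) + ["sports", "other"]
    code_flags = {}
    for code in matrix.codes:
        hits = lookup.flags_for(code)
        if code[:3] in sports:
            hits.add("sports")
        if not hits and code[0] in _EXTERNAL_CHAPTERS:
            hits.add("other")
        code_flags[code] = hits

    cols = {flag: np.zeros(len(matrix.patient_ids), dtype=bool) for flag in flag_names}
    for j, code in enumerate(matrix.codes):
        for flag in code_flags[code]:
            cols[flag] |= matrix.values[:, j].astype(bool)

    prof = pd.DataFrame(cols, index=matrix.patient_ids)
    meta = patients.set_index("patient_id").reindex(matrix.patient_ids)
    prof["age"] = meta["age"].astype(float)
    prof["rural"] = meta["rural"].astype(float)
    prof["income_quintile"] = meta["income_quintile"].astype(float)
    prof["severity"] = meta.get("severity", pd.Series("unspecified", index=meta.index)
                                ).fillna("unspecified")
    prof.index.name = "patient_id"
    return prof


def cause_severity_matrix(
    scores: FactorScoreMatrix,
    profiles: pd.DataFrame,
    sex_mask: np.ndarray,
    severity_levels: Sequence[str] = ("unspecified", "mild", "moderate", "severe"),
) -> pd.DataFrame:
    """Correlations of factor scores (+ age/rural/income) against cause
    flags and severity indicators for one sex's patients.

    Constant columns are excluded with a warning. The result feeds the
    rectangular FDR masking in :func:`codefactors.sexdiff.fdr_mask_rect`.
    """
    prof = profiles.reindex(scores.patient_ids).loc[sex_mask]
    left = scores.to_frame().loc[sex_mask].astype(float)
    for cov in ("age", "rural", "income_quintile"):
        left[cov] = prof[cov].to_numpy()
    flag_cols = [c for c in prof.columns
                 if c not in ("age", "rural", "income_quintile", "severity")]
    right = prof[flag_cols].astype(float)
    for level in severity_levels:
        right[f"severity_{level}"] = (prof["severity"] == level).astype(float)

    def _drop_constant(df: pd.DataFrame, side: str) -> pd.DataFrame:
        constant = [c for c in df.columns if df[c].nunique() <= 1]
        if constant:
            warnings.warn(f"constant {side} columns excluded: {constant}",
                          stacklevel=2)
        return df.drop(columns=constant)

    left = _drop_constant(left, "factor/covariate")
    right = _drop_constant(right, "cause/severity")
    ln = (left - left.mean()) / left.std(ddof=0)
    rn = (right - right.mean()) / right.std(ddof=0)
    corr = ln.T.to_numpy() @ rn.to_numpy() / len(left)
    return pd.DataFrame(corr, index=left.columns, columns=right.columns)


# --- exports -----------------------------------------------------------------


@dataclass
class HeatmapExport:
    values: pd.DataFrame  # reordered
    row_order: list[str]
    col_order: list[str]
    mask: pd.DataFrame | None = None


def export_heatmap(
    matrix: pd.DataFrame,
    tree_rows: LinkageTree,
    tree_cols: LinkageTree | None = None,
    mask: pd.DataFrame | None = None,
    path: str | Path | None = None,
    render: bool = False,
) -> HeatmapExport:
    """Reorder a matrix by dendrogram leaf order and optionally persist it.

    ``tree_cols`` defaults to reusing ``tree_rows`` for square matrices.
    The numeric export (values, orders, mask) is always written when a
    path is given; image rendering is optional and needs matplotlib.
    """
    tree_cols = tree_cols or tree_rows
    if tree_rows.n_items != matrix.shape[0] or tree_cols.n_items != matrix.shape[1]:
        raise ValueError("tree leaf counts do not match matrix shape")
    row_order = [matrix.index[i] for i in tree_rows.leaf_order]
    col_order = [matrix.columns[i] for i in tree_cols.leaf_order]
    ordered = matrix.loc[row_order, col_order]
    ordered_mask = mask.loc[row_order, col_order] if mask is not None else None
    if path is not None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        ordered.to_csv(path / "values.csv")
        (path / "row_order.txt").write_text("\n".join(map(str, row_order)) + "\n")
        (path / "col_order.txt").write_text("\n".join(map(str, col_order)) + "\n")
        if ordered_mask is not None:
            ordered_mask.to_csv(path / "mask.csv")
        if render:
            _render_png(ordered, ordered_mask, path / "heatmap.png")
    return HeatmapExport(values=ordered, row_order=list(map(str, row_order)),
                         col_order=list(map(str, col_order)), mask=ordered_mask)


def _render_png(values: pd.DataFrame, mask: pd.DataFrame | None, out: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = values.to_numpy(dtype=float).copy()
    if mask is not None:
        data[mask.to_numpy(dtype=bool)] = np.nan
    fig, ax = plt.subplots(figsize=(8, 8))
    im = ax.imshow(data, cmap="RdBu_r", vmin=-1, vmax=1)
    ax.set_xticks(range(len(values.columns)), values.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(len(values.index)), values.index, fontsize=6)
    fig.colorbar(im, ax=ax, shrink=0.7)
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)


def wordcloud_weights(
    scores: FactorScoreMatrix,
    fits: Sequence[CLRFit] | None,
    sex_mask: np.ndarray,
    weight_kind: str = "proportion",
    or_cap: float = 100.0,
) -> pd.DataFrame:
    """Per-factor word weights for one sex, sorted descending.

    ``proportion`` weights are mean factor scores among the selected
    patients; ``odds_ratio`` weights come from the fitted ORs (infinite
    ORs are capped at ``or_cap`` and flagged).
    """
    if weight_kind == "proportion":
        vals = scores.values[sex_mask].mean(axis=0)
        table = pd.DataFrame({"factor_id": scores.factor_ids, "weight": vals,
                              "capped": False})
    elif weight_kind == "odds_ratio":
        if fits is None:
            raise ValueError("odds_ratio weights need CLR fits")
        by_id = {f.factor_id: f for f in fits}
        missing = [f for f in scores.factor_ids if f not in by_id]
        if missing:
            raise ValueError(f"missing fits for factors: {missing}")
        rows = []
        for fid in scores.factor_ids:
            or_value = by_id[fid].or_value
            capped = not np.isfinite(or_value)
            rows.append((fid, min(or_value, or_cap), capped))
        table = pd.DataFrame(rows, columns=["factor_id", "weight", "capped"])
    else:
        raise ValueError(f"unknown weight kind {weight_kind!r}")
    table["weight_kind"] = weight_kind
    return table.sort_values("weight", ascending=False, ignore_index=True)
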