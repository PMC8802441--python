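"""Matched-cohort data model: index dates, event-window detection, code
binarization, and pair-preserving dataset splits.

Calendar time is integer days throughout; an event window is an inclusive
range of day offsets around each patient's index date.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CASE_CODE_PREFIXES",
    "CodeMatrix",
    "DatasetSplit",
    "EventWindow",
    "PairIndex",
    "binarize_codes",
    "derive_index_date",
    "detect_event_window",
    "normalize_code",
    "split_pairs",
    "validate_patients",
]

# Default case-defining diagnosis prefixes (head-injury admissions); dots
# stripped, matched as prefixes against normalized code strings.
CASE_CODE_PREFIXES = (
    "S020", "S021", "S023", "S027", "S028", "S029", "S040", "S071", "S06",
)

_CODE3_RE = re.compile(r"^[A-Z][0-9]{2}$")

EXCLUDED_CATEGORIES = ("U98", "U99")


def normalize_code(code: str) -> str:
    """Uppercase a raw code string and strip dots (``'s06.0' -> 'S060'``)."""
    return str(code).replace(".", "").strip().upper()


@dataclass(frozen=True)
class EventWindow:
    """Inclusive day-offset window around the index date."""

    days_before: int
    days_after: int

    def __post_init__(self) -> None:
        if self.days_before < 0 or self.days_after < 0:
            raise ValueError("window extents must be non-negative")

    @property
    def length(self) -> int:
        return self.days_before + self.days_after + 1

    def contains(self, offset: int) -> bool:
        return -self.days_before <= offset <= self.days_after


@dataclass
class CodeMatrix:
    """Binary patients-by-code matrix for one event window.

    ``values[i, j] == 1`` iff patient ``patient_ids[i]`` has at least one
    in-window visit carrying a code whose three-character category equals
    ``codes[j]``.
    """

    patient_ids: list[str]
    codes: list[str]
    values: np.ndarray
    window: EventWindow | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.uint8)
        if self.values.shape != (len(self.patient_ids), len(self.codes)):
            raise ValueError("values shape does not match ids")
        if len(set(self.codes)) != len(self.codes):
            raise ValueError("duplicate code columns")
        self._row_of = {p: i for i, p in enumerate(self.patient_ids)}
        self._col_of = {c: j for j, c in enumerate(self.codes)}

    def row(self, patient_id: str) -> np.ndarray:
        return self.values[self._row_of[patient_id]]

    def column(self, code: str) -> np.ndarray:
        try:
            return self.values[:, self._col_of[code]]
        except KeyError:
            raise KeyError(f"code {code!r} not in matrix") from None

    def has_code(self, code: str) -> bool:
        return code in self._col_of

    def restrict(self, codes: Sequence[str]) -> "CodeMatrix":
        """Sub-matrix keeping only ``codes``, in the given order."""
        idx = [self._col_of[c] for c in codes]
        return CodeMatrix(self.patient_ids, list(codes), self.values[:, idx], self.window)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.patient_ids, columns=self.codes)


def validate_patients(patients: pd.DataFrame) -> None:
    """Check the matched-pair invariants of a patient table.

    Each ``pair_id`` must contain exactly one case and one reference and
    the two members must agree on sex, age, rurality, and income quintile.
    """
    required = {"patient_id", "pair_id", "cohort_arm", "sex", "age",
                "income_quintile", "rural", "index_date"}
    missing = required - set(patients.columns)
    if missing:
        raise ValueError(f"patient table missing columns: {sorted(missing)}")
    arms = patients.groupby("pair_id")["cohort_arm"].agg(list)
    bad = [p for p, a in arms.items() if sorted(a) != ["case", "reference"]]
    if bad:
        raise ValueError(f"pairs without exactly one case and one reference: {bad[:10]}")
    for col in ("sex", "age", "rural", "income_quintile"):
        per_pair = patients.groupby("pair_id")[col].nunique(dropna=False)
        bad = per_pair[per_pair > 1].index.tolist()
        if bad:
            raise ValueError(f"pairs mismatched on {col}: {bad[:10]}")


def derive_index_date(
    visits: pd.DataFrame,
    arm: str,
    case_code_prefixes: Sequence[str] = CASE_CODE_PREFIXES,
) -> int:
    """Derive the index date from one patient's visit rows.

    Cases anchor on the earliest visit carrying a case-defining code;
    references use the midpoint (floor) of their first and last visit dates.
    """
    if visits.empty:
        raise ValueError("cannot derive an index date without visits")
    dates = visits["visit_date"].astype(int)
    if arm == "reference":
        return int((dates.min() + dates.max()) // 2)
    if arm != "case":
        raise ValueError(f"unknown cohort arm {arm!r}")
    norm = visits["code"].map(normalize_code)
    prefixes = tuple(normalize_code(p) for p in case_code_prefixes)
    is_case_visit = norm.str.startswith(prefixes)
    if not bool(is_case_visit.any()):
        pid = visits["patient_id"].iloc[0] if "patient_id" in visits else "<unknown>"
        raise ValueError(f"case patient {pid} has no case-defining code")
    return int(dates[is_case_visit].min())


def _moving_median(values: np.ndarray, width: int) -> np.ndarray:
    half = width // 2
    out = np.empty_like(values, dtype=float)
    n = len(values)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[i] = np.median(values[lo:hi])
    return out


def detect_event_window(
    offset_histogram: Mapping[int, float],
    baseline_span: tuple[int, int] | None = None,
    tolerance_k: float = 2.0,
    smooth_window: int = 7,
    min_stable_run: int | None = None,
) -> EventWindow:
    """Locate where the visit-frequency peak around offset 0 flattens out.

    The histogram is smoothed with a centred moving median; the baseline
    level is the median of the smoothed counts over the outer third of the
    span on each side, with spread estimated by the scaled median absolute
    deviation (MAD x 1.4826). Scanning outward from 0 on each side, the
    boundary is the first offset from which every further smoothed count
    stays within ``tolerance_k`` robust deviations of the baseline median.
    ``min_stable_run`` relaxes "every further offset" to a run of that many
    consecutive offsets, which makes the scan robust to isolated baseline
    fluctuations far from the peak on noisy histograms.
    """
    if not offset_histogram:
        raise ValueError("empty histogram")
    lo = min(offset_histogram) if baseline_span is None else baseline_span[0]
    hi = max(offset_histogram) if baseline_span is None else baseline_span[1]
    if lo > 0 or hi < 0:
        raise ValueError("histogram span must cover offset 0 on both sides")
    offsets = np.arange(lo, hi + 1)
    counts = np.array([float(offset_histogram.get(int(t), 0.0)) for t in offsets])
    smoothed = _moving_median(counts, smooth_window)

    third_neg = max(1, (-lo) // 3)
    third_pos = max(1, hi // 3)
    base_mask = (offsets <= lo + third_neg) | (offsets >= hi - third_pos)
    base_vals = smoothed[base_mask]
    baseline = float(np.median(base_vals))
    robust = 1.4826 * float(np.median(np.abs(base_vals - baseline)))
    tol = tolerance_k * robust

    within = np.abs(smoothed - baseline) <= tol

    def _first_stable(side: np.ndarray) -> int:
        # side[0] is offset 0 moving outward; find the first index from
        # which the band holds for the required run (default: rest of span).
        n = side.size
        run_len = n if min_stable_run is None else min(min_stable_run, n)
        for t in range(n):
            end = min(n, t + run_len)
            if bool(side[t:end].all()):
                return t
        raise ValueError(
            "histogram never settles to baseline within the span; widen it"
        )

    zero = int(-lo)
    days_after = _first_stable(within[zero:])
    days_before = _first_stable(within[zero::-1])
    return EventWindow(days_before=days_before, days_after=days_after)


def binarize_codes(
    visits: pd.DataFrame,
    patients: pd.DataFrame,
    window: EventWindow,
) -> CodeMatrix:
    """Binarize three-character code categories over the event window.

    Every patient in ``patients`` gets a row (all-zero if nothing falls in
    their window). Columns are the three-character categories observed
    anywhere in ``visits`` minus the provisional categories U98/U99.
    """
    unknown = set(visits["patient_id"]) - set(patients["patient_id"])
    if unknown:
        raise ValueError(f"visits reference unknown patients: {sorted(unknown)[:10]}")

    norm = visits["code"].map(normalize_code)
    bad = sorted(set(norm[~norm.str.slice(0, 3).str.match(_CODE3_RE)]))
    if bad:
        raise ValueError(f"malformed code strings: {bad[:20]}")
    cat = norm.str.slice(0, 3)

    universe = sorted(set(cat) - set(EXCLUDED_CATEGORIES))
    patient_ids = list(patients["patient_id"])
    col_of = {c: j for j, c in enumerate(universe)}
    row_of = {p: i for i, p in enumerate(patient_ids)}

    idx = patients.set_index("patient_id")["index_date"].astype(int)
    offset = visits["visit_date"].astype(int).to_numpy() - idx.reindex(
        visits["patient_id"]).to_numpy()
    in_window = (offset >= -window.days_before) & (offset <= window.days_after)
    keep = in_window & cat.isin(col_of).to_numpy()

    values = np.zeros((len(patient_ids), len(universe)), dtype=np.uint8)
    rows = visits.loc[keep, "patient_id"].map(row_of).to_numpy()
    cols = cat[keep].map(col_of).to_numpy()
    values[rows, cols] = 1
    return CodeMatrix(patient_ids, universe, values, window)


@dataclass
class DatasetSplit:
    """Pair-level assignment to training/validation/testing."""

    assignment: dict[str, str]
    fractions: tuple[float, ...]
    seed: int
    names: tuple[str, ...] = ("training", "validation", "testing")

    def pair_ids(self, name: str) -> list[str]:
        return [p for p, n in self.assignment.items() if n == name]


def _largest_remainder_sizes(n: int, fractions: Sequence[float]) -> list[int]:
    exact = [n * f for f in fractions]
    sizes = [int(np.floor(e)) for e in exact]
    short = n - sum(sizes)
    order = np.argsort([-(e - s) for e, s in zip(exact, sizes)], kind="stable")
    for i in order[:short]:
        sizes[int(i)] += 1
    return sizes


def split_pairs(
    pair_ids: Sequence[str],
    fractions: tuple[float, float, float] = (0.5, 0.25, 0.25),
    seed: int = 0,
    names: tuple[str, str, str] = ("training", "validation", "testing"),
) -> DatasetSplit:
    """Randomly split pairs into contiguous blocks sized by largest-remainder
    rounding of the fractions; both pair members share the assignment."""
    if any(f <= 0 for f in fractions):
        raise ValueError("fractions must be positive")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    if len(pair_ids) < len(fractions):
        raise ValueError("fewer pairs than partitions")
    rng = np.random.default_rng(seed)
    perm = list(np.array(pair_ids, dtype=object)[rng.permutation(len(pair_ids))])
    sizes = _largest_remainder_sizes(len(perm), fractions)
    assignment: dict[str, str] = {}
    start = 0
    for name, size in zip(names, sizes):
        for p in perm[start:start + size]:
            assignment[str(p)] = name
        start += size
    return DatasetSplit(assignment=assignment, fractions=tuple(fractions),
                        seed=seed, names=tuple(names))


@dataclass
class PairIndex:
    """Aligned case/reference row positions of a CodeMatrix, one per pair."""

    pair_ids: list[str]
    case_rows: np.ndarray
    ref_rows: np.ndarray

    @classmethod
    def from_patients(cls, patients: pd.DataFrame, matrix: CodeMatrix) -> "PairIndex":
        row_of = {p: i for i, p in enumerate(matrix.patient_ids)}
        cases = patients[patients["cohort_arm"] == "case"].set_index("pair_id")["patient_id"]
        refs = patients[patients["cohort_arm"] == "reference"].set_index("pair_id")["patient_id"]
        pair_ids = sorted(set(cases.index) & set(refs.index))
        missing = [p for p in pair_ids
                   if cases[p] not in row_of or refs[p] not in row_of]
        if missing:
            raise ValueError(f"pairs incomplete in matrix: {missing[:10]}")
        case_rows = np.array([row_of[cases[p]] for p in pair_ids], dtype=np.intp)
        ref_rows = np.array([row_of[refs[p]] for p in pair_ids], dtype=np.intp)
        return cls(pair_ids=list(pair_ids), case_rows=case_rows, ref_rows=ref_rows)

    def __len__(self) -> int:
        return len(self.pair_ids)
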