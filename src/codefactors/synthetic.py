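"""Synthetic matched case-reference cohorts with planted ground truth.

Every downstream stage of the pipeline is testable against this generator:
it plants latent factor blocks of codes with known case-vs-reference odds
ratios, sex-specific between-factor correlations (via a Gaussian copula on
the latent normals), and visit-date histograms that peak at the index date
and settle to baseline at a configurable stationary offset.

The case activation probability for a factor with baseline ``p_ref`` and
target odds ratio ``OR`` solves ``logit(p_case) = logit(p_ref) + ln(OR)``.
Matching covariates are drawn once per pair and copied to both members, so
matching is exact by construction.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from . import io as cfio

__all__ = [
    "FactorBlueprint",
    "GroundTruth",
    "SimulationConfig",
    "WindowShape",
    "case_probability",
    "generate_cohort",
    "generate_emissions",
    "generate_visit_offsets",
    "write_fixture",
]


def case_probability(p_ref: float, target_or: float) -> float:
    """Solve logit(p_case) = logit(p_ref) + ln(OR)."""
    return float(special.expit(special.logit(p_ref) + np.log(target_or)))


@dataclass(frozen=True)
class WindowShape:
    """Visit-rate shape around the index date.

    Expected visits per day are ``baseline_rate + max(0, peak_height -
    decay_rate * |offset|)`` over ``offset in [-span, span]``. A zero decay
    rate makes the shape flat (uniform offsets); otherwise the excess
    reaches zero at ``peak_height / decay_rate`` days on each side.
    """

    peak_height: float = 3.0
    decay_rate: float = 0.1
    baseline_rate: float = 0.05
    span: int = 90

    def __post_init__(self) -> None:
        if self.baseline_rate <= 0:
            raise ValueError("baseline rate must be positive")
        if self.peak_height < 0 or self.decay_rate < 0:
            raise ValueError("peak height and decay rate must be non-negative")
        if self.span < 1:
            raise ValueError("span must be at least 1 day")

    @property
    def stationary_extent(self) -> int | None:
        """Offset at which the excess rate reaches zero, if it ever does."""
        if self.peak_height == 0:
            return 0
        if self.decay_rate == 0:
            return None
        return int(np.ceil(self.peak_height / self.decay_rate))

    def rate(self, offsets: np.ndarray) -> np.ndarray:
        excess = np.clip(self.peak_height - self.decay_rate * np.abs(offsets), 0, None)
        return self.baseline_rate + excess

    def excess(self, offsets: np.ndarray) -> np.ndarray:
        return np.clip(self.peak_height - self.decay_rate * np.abs(offsets), 0, None)

    @classmethod
    def with_stationary_point(cls, peak_height: float, days: int = 30,
                              baseline_rate: float = 0.05, span: int = 90
                              ) -> "WindowShape":
        """Shape whose excess decays linearly to zero exactly at ``days``."""
        return cls(peak_height=peak_height, decay_rate=peak_height / days,
                   baseline_rate=baseline_rate, span=span)


def generate_visit_offsets(
    n_visits: int,
    shape: WindowShape,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Sample day offsets with probability proportional to the shape's rate."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    offsets = np.arange(-shape.span, shape.span + 1)
    rate = shape.rate(offsets)
    return rng.choice(offsets, size=n_visits, p=rate / rate.sum())


@dataclass(frozen=True)
class FactorBlueprint:
    """One planted factor: a block of codes driven by a latent activation."""

    factor_id: str
    code_ids: tuple[str, ...]
    p_ref: float
    target_or: float
    q_on: float
    q_bg: float
    haddon_categories: frozenset[str] = frozenset({"host"})

    def __post_init__(self) -> None:
        object.__setattr__(self, "code_ids", tuple(self.code_ids))
        if not self.code_ids:
            raise ValueError(f"{self.factor_id}: needs at least one code")
        if not 0 < self.p_ref < 1:
            raise ValueError(f"{self.factor_id}: p_ref must lie in (0, 1)")
        if self.target_or <= 0:
            raise ValueError(f"{self.factor_id}: target OR must be positive")
        if not 0 < self.q_on <= 1:
            raise ValueError(f"{self.factor_id}: q_on must lie in (0, 1]")
        if not 0 <= self.q_bg < self.q_on:
            raise ValueError(f"{self.factor_id}: need 0 <= q_bg < q_on")

    @property
    def p_case(self) -> float:
        return case_probability(self.p_ref, self.target_or)


@dataclass
class SimulationConfig:
    n_pairs_by_sex: Mapping[str, int]
    blueprints: Sequence[FactorBlueprint] = ()
    n_noise_codes: int = 0
    noise_prevalence: float = 0.05
    correlation_targets: Sequence[tuple[str, str, float, float]] = ()
    window_shape: WindowShape = field(default_factory=WindowShape)
    seed: int = 0
    study_days: int = 2000
    case_code: str = "S06"
    filler_code: str = "Z00"
    rural_prob: float = 0.15
    assign_severity: bool = False

    def __post_init__(self) -> None:
        self.n_pairs_by_sex = dict(self.n_pairs_by_sex)
        for sex, n in self.n_pairs_by_sex.items():
            if sex not in ("F", "M"):
                raise ValueError(f"unknown sex label {sex!r}")
            if n < 1:
                raise ValueError("need at least one pair per configured sex")
        ids = [bp.factor_id for bp in self.blueprints]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate blueprint factor ids")
        seen: set[str] = set()
        for bp in self.blueprints:
            overlap = seen & set(bp.code_ids)
            if overlap:
                raise ValueError(f"codes in multiple blueprints: {sorted(overlap)}")
            seen |= set(bp.code_ids)
        if self.case_code[:3] in {c[:3] for c in seen}:
            raise ValueError("blueprint codes collide with the case-defining code")
        if self.n_noise_codes and not 0 < self.noise_prevalence < 1:
            raise ValueError("noise prevalence must lie in (0, 1)")
        declared = set(ids)
        for f, g, rho_f, rho_m in self.correlation_targets:
            if f not in declared or g not in declared:
                raise ValueError(f"correlation target references unknown factors ({f}, {g})")
            if f == g:
                raise ValueError("correlation target must involve two distinct factors")
            if max(abs(rho_f), abs(rho_m)) >= 1:
                raise ValueError(f"|rho| must be < 1 for pair ({f}, {g})")

    def factor_ids(self) -> list[str]:
        return [bp.factor_id for bp in self.blueprints]


@dataclass
class GroundTruth:
    """Planted signal of a simulation, for validating downstream stages."""

    signal_code_ids: set[str]
    code_to_factor: dict[str, str]
    factor_or: dict[str, float]
    pair_rho_by_sex: dict[tuple[str, str, str], float]
    noise_code_ids: set[str]
    case_code: str
    filler_code: str
    activations: pd.DataFrame | None = None  # patients x factors, binary
    latents: pd.DataFrame | None = None  # patients x factors, latent normals


def _correlation_matrix(config: SimulationConfig, sex: str) -> np.ndarray:
    ids = config.factor_ids()
    k = len(ids)
    R = np.eye(k)
    pos = {f: i for i, f in enumerate(ids)}
    for f, g, rho_f, rho_m in config.correlation_targets:
        rho = rho_f if sex == "F" else rho_m
        R[pos[f], pos[g]] = R[pos[g], pos[f]] = rho
    if k and np.linalg.eigvalsh(R).min() < -1e-10:
        pairs = [(f, g) for f, g, *_ in config.correlation_targets]
        raise ValueError(
            f"infeasible correlation targets for sex {sex}: the latent "
            f"correlation matrix over pairs {pairs} is not positive "
            f"semi-definite")
    return R


def _noise_code_labels(config: SimulationConfig) -> list[str]:
    if config.n_noise_codes == 0:
        return []
    reserved = {c[:3] for bp in config.blueprints for c in bp.code_ids}
    reserved |= {config.case_code[:3], config.filler_code[:3], "U98", "U99"}
    labels: list[str] = []
    for letter in string.ascii_uppercase:
        for i in range(100):
            code = f"{letter}{i:02d}"
            if code not in reserved:
                labels.append(code)
            if len(labels) == config.n_noise_codes:
                return labels
    raise ValueError("too many noise codes requested")


def generate_emissions(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Covariates, per-patient binary code emissions, and the ground truth.

    This is the code-level output of the generator, before visit-date
    synthesis: a patient table and a patients-by-codes 0/1 frame recording
    which codes will be laid down inside each patient's event window.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_cov, rng_lat, rng_code, _ = [np.random.default_rng(s) for s in ss.spawn(4)]

    noise_codes = _noise_code_labels(config)
    factor_ids = config.factor_ids()
    signal_codes = [c for bp in config.blueprints for c in bp.code_ids]
    all_codes = signal_codes + noise_codes

    patient_rows = []
    emission_blocks = []
    activation_blocks = []
    latent_blocks = []
    index_of = {f: i for i, f in enumerate(factor_ids)}

    for sex in ("F", "M"):
        n = config.n_pairs_by_sex.get(sex, 0)
        if n == 0:
            continue
        # pair-level covariates, copied to both members (exact matching)
        comp = rng_cov.random(n) < 0.5
        age = np.where(comp, rng_cov.normal(25, 8, n), rng_cov.normal(70, 10, n))
        age = np.clip(np.round(age, 1), 0.0, 105.0)
        income = rng_cov.integers(1, 6, n)
        rural = rng_cov.random(n) < config.rural_prob
        idx_case = rng_cov.integers(config.window_shape.span,
                                    config.study_days - config.window_shape.span, n)
        idx_ref = rng_cov.integers(config.window_shape.span,
                                   config.study_days - config.window_shape.span, n)

        K = len(factor_ids)
        R = _correlation_matrix(config, sex)
        if K:
            chol = np.linalg.cholesky(R + 1e-12 * np.eye(K))
            z_case = rng_lat.standard_normal((n, K)) @ chol.T
            z_ref = rng_lat.standard_normal((n, K)) @ chol.T
        else:
            z_case = np.zeros((n, 0))
            z_ref = np.zeros((n, 0))
        thr_ref = np.array([stats.norm.ppf(bp.p_ref) for bp in config.blueprints])
        thr_case = np.array([stats.norm.ppf(bp.p_case) for bp in config.blueprints])
        act_case = z_case < thr_case
        act_ref = z_ref < thr_ref

        for arm, acts, lat, idx in (("case", act_case, z_case, idx_case),
                                    ("reference", act_ref, z_ref, idx_ref)):
            emit = np.zeros((n, len(all_codes)), dtype=np.uint8)
            col = 0
            for bp in config.blueprints:
                m = len(bp.code_ids)
                p = np.where(acts[:, [index_of[bp.factor_id]]], bp.q_on, bp.q_bg)
                emit[:, col:col + m] = rng_code.random((n, m)) < p
                col += m
            if noise_codes:
                emit[:, col:] = rng_code.random((n, len(noise_codes))) < config.noise_prevalence
            suffix = "C" if arm == "case" else "R"
            pids = [f"{sex}{i:06d}{suffix}" for i in range(n)]
            for i, pid in enumerate(pids):
                patient_rows.append((pid, f"{sex}{i:06d}", arm, sex, age[i],
                                     int(income[i]), bool(rural[i]), int(idx[i])))
            emission_blocks.append(pd.DataFrame(emit, index=pids, columns=all_codes))
            activation_blocks.append(pd.DataFrame(acts.astype(np.uint8), index=pids,
                                                  columns=factor_ids))
            latent_blocks.append(pd.DataFrame(lat, index=pids, columns=factor_ids))

    patients = pd.DataFrame(patient_rows, columns=[
        "patient_id", "pair_id", "cohort_arm", "sex", "age",
        "income_quintile", "rural", "index_date"])
    if config.assign_severity:
        sev = np.array(["unspecified", "mild", "moderate", "severe"])
        draws = rng_cov.choice(sev, size=len(patients), p=(0.43, 0.35, 0.04, 0.18))
        patients["severity"] = np.where(patients["cohort_arm"] == "case",
                                        draws, "unspecified")
    emissions = pd.concat(emission_blocks) if emission_blocks else pd.DataFrame()
    truth = GroundTruth(
        signal_code_ids=set(signal_codes),
        code_to_factor={c: bp.factor_id for bp in config.blueprints for c in bp.code_ids},
        factor_or={bp.factor_id: bp.target_or for bp in config.blueprints},
        pair_rho_by_sex={(f, g, s): (rf if s == "F" else rm)
                         for f, g, rf, rm in config.correlation_targets
                         for s in ("F", "M")},
        noise_code_ids=set(noise_codes),
        case_code=config.case_code,
        filler_code=config.filler_code,
        activations=pd.concat(activation_blocks) if activation_blocks else None,
        latents=pd.concat(latent_blocks) if latent_blocks else None,
    )
    return patients, emissions, truth


def _code_offsets(n: int, shape: WindowShape, rng: np.random.Generator) -> np.ndarray:
    """Offsets for code-bearing visits, drawn from the excess (peak) part of
    the shape so emitted codes always land inside the event window."""
    ext = shape.stationary_extent
    ext = min(shape.span, ext if ext not in (None, 0) else 30)
    offsets = np.arange(-ext, ext + 1)
    w = shape.excess(offsets)
    p = w / w.sum() if w.sum() > 0 else np.full(offsets.size, 1.0 / offsets.size)
    return rng.choice(offsets, size=n, p=p)


def generate_cohort(config: SimulationConfig
                    ) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate the patient table, long-format visit table, and ground truth.

    Baseline visits (bearing only the filler code) arrive uniformly over
    the shape's span at the baseline rate; every emitted code gets a visit
    at an offset drawn from the peak's excess distribution; cases carry the
    case-defining code on the index date itself.
    """
    patients, emissions, truth = generate_emissions(config)
    ss = np.random.SeedSequence(config.seed)
    rng_vis = np.random.default_rng(ss.spawn(4)[3])
    shape = config.window_shape

    pids = emissions.index.to_numpy()
    index_dates = patients.set_index("patient_id")["index_date"].reindex(pids).to_numpy()

    # baseline (filler) visits: uniform over the span
    span_days = 2 * shape.span + 1
    n_base = rng_vis.poisson(shape.baseline_rate * span_days, size=len(pids))
    base_pid = np.repeat(pids, n_base)
    base_idx = np.repeat(index_dates, n_base)
    base_off = rng_vis.integers(-shape.span, shape.span + 1, size=int(n_base.sum()))

    # code-bearing visits
    rows, cols = np.nonzero(emissions.to_numpy())
    code_pid = pids[rows]
    code_idx = index_dates[rows]
    code_lab = emissions.columns.to_numpy()[cols]
    code_off = _code_offsets(len(rows), shape, rng_vis)

    # case-defining visit at offset 0 for every case
    case_mask = patients["cohort_arm"].to_numpy() == "case"
    case_pids = patients.loc[case_mask, "patient_id"].to_numpy()
    case_idx = patients.loc[case_mask, "index_date"].to_numpy()

    visits = pd.DataFrame({
        "patient_id": np.concatenate([base_pid, code_pid, case_pids]),
        "visit_date": np.concatenate([base_idx + base_off, code_idx + code_off,
                                      case_idx]).astype(int),
        "code": np.concatenate([np.full(len(base_pid), config.filler_code),
                                code_lab, np.full(len(case_pids), config.case_code)]),
    })

    # every patient needs at least one visit for an index to be derivable
    seen = set(visits["patient_id"])
    orphans = [p for p in pids if p not in seen]
    if orphans:
        orphan_idx = patients.set_index("patient_id")["index_date"].reindex(orphans)
        extra = pd.DataFrame({"patient_id": orphans,
                              "visit_date": orphan_idx.to_numpy().astype(int),
                              "code": config.filler_code})
        visits = pd.concat([visits, extra], ignore_index=True)

    visits = visits.sort_values(["patient_id", "visit_date", "code"],
                                kind="stable", ignore_index=True)
    return patients, visits, truth


def write_fixture(
    patients: pd.DataFrame,
    visits: pd.DataFrame,
    truth: GroundTruth,
    directory: str | Path,
) -> dict[str, Path]:
    """Persist the three artifacts as delimited/structured text."""
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
        paths = {
            "patients": cfio.write_patients(patients, directory / "patients.csv"),
            "visits": cfio.write_visits(visits, directory / "visits.csv"),
            "ground_truth": cfio.write_ground_truth(truth, directory / "ground_truth.json"),
        }
    except OSError as exc:
        raise OSError(f"failed writing fixture under {directory}: {exc}") from exc
    return paths
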