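"""Self-contained simulation experiments behind the acceptance checks.

Each function recomputes one headline quantity from scratch by running the
pipeline on generated data: event-window length on a peaked histogram,
false-discovery control of the screening stage, confidence-interval
coverage and parameter recovery on planted signals, and the size of the
sex-difference correlation test under the null.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .association import fit_conditional_logit
from .cohort import CodeMatrix, PairIndex, detect_event_window
from .factors import define_factors, fit_pca_factors
from .screening import DiscordantCounts, by_adjust, discordant_table, mcnemar_test
from .sexdiff import phi_matrix, z_difference
from .synthetic import FactorBlueprint, SimulationConfig, generate_emissions

__all__ = [
    "ci_coverage_simulation",
    "detected_window_length",
    "factor_recovery_simulation",
    "percent",
    "screening_fdr_simulation",
    "sexdiff_detection_simulation",
    "type_i_error_simulation",
]


def percent(numerator: float, denominator: float, digits: int = 0) -> float:
    """Percentage rounded to ``digits`` decimals (0 -> nearest integer)."""
    value = round(100.0 * numerator / denominator, digits)
    return value if digits else float(int(value))


def detected_window_length(baseline: float = 10.0, peak: float = 100.0,
                           days: int = 30, span: int = 90) -> int:
    """Run the window detector on a deterministic histogram whose visit
    frequency peaks at offset 0 and decays linearly to baseline at ``days``
    on each side; returns the detected window length in days."""
    hist = {}
    for d in range(-span, span + 1):
        excess = max(0.0, peak * (1.0 - abs(d) / days))
        hist[d] = baseline + excess
    window = detect_event_window(hist)
    return window.length


def _pairs_from_patients(patients, matrix: CodeMatrix) -> PairIndex:
    return PairIndex.from_patients(patients, matrix)


def screening_fdr_simulation(
    n_reps: int = 200,
    seed: int = 0,
    n_pairs: int = 2000,
    n_null: int = 500,
    n_signal: int = 50,
    signal_or: float = 2.0,
    signal_p_ref: float = 0.10,
    null_prevalence: float = 0.05,
    q: float = 0.05,
) -> float:
    """Mean false-discovery proportion (in %) of the matched McNemar + BY
    screening stage over seeded replicates of a null+signal cohort."""
    blueprints = [FactorBlueprint(f"S{i:03d}", (_signal_code(i),),
                                  p_ref=signal_p_ref, target_or=signal_or,
                                  q_on=1.0, q_bg=0.0)
                  for i in range(n_signal)]
    fdps = []
    for rep in range(n_reps):
        config = SimulationConfig(
            n_pairs_by_sex={"F": n_pairs // 2, "M": n_pairs - n_pairs // 2},
            blueprints=blueprints, n_noise_codes=n_null,
            noise_prevalence=null_prevalence, seed=seed * 1_000_003 + rep)
        patients, emissions, truth = generate_emissions(config)
        matrix = CodeMatrix(list(emissions.index), list(emissions.columns),
                            emissions.to_numpy())
        pairs = _pairs_from_patients(patients, matrix)
        tab = discordant_table(matrix, pairs)
        p_values = [mcnemar_test(DiscordantCounts(code, int(b), int(c), len(pairs))
                                 ).p_value
                    for code, b, c in zip(tab["code"], tab["b"], tab["c"])]
        outcome = by_adjust(p_values, q=q, ids=list(tab["code"]))
        rejected = set(outcome.rejected)
        false_rejections = len(rejected & truth.noise_code_ids)
        fdps.append(false_rejections / max(1, len(rejected)))
    return 100.0 * float(np.mean(fdps))


def _signal_code(i: int) -> str:
    # valid three-character categories S00..S99 are reserved for signal
    return f"T{i % 100:02d}" if i < 100 else f"S{i - 100:02d}"


def ci_coverage_simulation(
    n_reps: int = 500,
    seed: int = 0,
    n_pairs: int = 2000,
    p_ref: float = 0.15,
    target_or: float = 2.0,
) -> float:
    """Fraction of replicates whose conditional-logistic 95% CI contains
    the planted odds ratio."""
    covered = 0
    for rep in range(n_reps):
        config = SimulationConfig(
            n_pairs_by_sex={"F": n_pairs // 2, "M": n_pairs - n_pairs // 2},
            blueprints=[FactorBlueprint("T", ("T00",), p_ref=p_ref,
                                        target_or=target_or, q_on=1.0, q_bg=0.0)],
            seed=seed * 1_000_003 + rep)
        patients, emissions, _ = generate_emissions(config)
        matrix = CodeMatrix(list(emissions.index), ["T00"], emissions.to_numpy())
        pairs = _pairs_from_patients(patients, matrix)
        from .factors import FactorScoreMatrix
        scores = FactorScoreMatrix(matrix.patient_ids, ["T"], matrix.values)
        fit = fit_conditional_logit(scores, pairs, "T")
        if fit.ci95[0] <= target_or <= fit.ci95[1]:
            covered += 1
    return covered / n_reps


def factor_recovery_simulation(
    n_reps: int = 100,
    seed: int = 0,
    n_patients: int = 5000,
    codes_per_factor: int = 8,
    cutoff: float = 0.2,
) -> float:
    """Fraction of planted signal codes assigned to their true factor by
    the loading cutoff, averaged over replicates.

    Block strengths are graded across the four factors: with identical
    strengths the leading eigenvalues are degenerate and an unrotated
    loading basis cannot identify the blocks at all.
    """
    letters = "ABCD"
    blueprints = [FactorBlueprint(
        f"L{i}", tuple(f"{letters[i]}{j:02d}" for j in range(codes_per_factor)),
        p_ref=0.10 + 0.05 * i, target_or=2.0, q_on=0.95 - 0.15 * i, q_bg=0.02)
        for i in range(4)]
    accuracies = []
    n_pairs = n_patients // 4  # patients = 2 sexes x 2 arms x pairs
    for rep in range(n_reps):
        config = SimulationConfig(
            n_pairs_by_sex={"F": n_pairs, "M": n_pairs},
            blueprints=blueprints, seed=seed * 1_000_003 + rep)
        _, emissions, truth = generate_emissions(config)
        matrix = CodeMatrix(list(emissions.index), list(emissions.columns),
                            emissions.to_numpy())
        model = fit_pca_factors(matrix)
        definitions, _ = define_factors(model, 4, cutoff=cutoff, warn_empty=False)
        blocks: dict[str, set[str]] = {}
        for code, fid in truth.code_to_factor.items():
            blocks.setdefault(fid, set()).add(code)
        matched = {d.factor_id: max(blocks, key=lambda f: len(blocks[f] & d.code_ids))
                   for d in definitions}
        correct = 0
        for code, fid in truth.code_to_factor.items():
            holders = [d for d in definitions if code in d.code_ids]
            if any(matched[d.factor_id] == fid for d in holders):
                correct += 1
        accuracies.append(correct / len(truth.code_to_factor))
    return float(np.mean(accuracies))


def sexdiff_detection_simulation(
    n_reps: int = 100,
    seed: int = 0,
    n_pairs_per_sex: int = 2000,
    rho_f: float = 0.6,
    rho_m: float = 0.1,
    q: float = 0.05,
) -> float:
    """Fraction of replicates where the planted sex-specific correlation
    difference survives the Fisher difference test plus BY masking."""
    blueprints = [FactorBlueprint(f"L{i}", (f"T{i:02d}",), p_ref=0.3,
                                  target_or=1.5, q_on=1.0, q_bg=0.0)
                  for i in range(4)]
    detected = 0
    for rep in range(n_reps):
        config = SimulationConfig(
            n_pairs_by_sex={"F": n_pairs_per_sex, "M": n_pairs_per_sex},
            blueprints=blueprints,
            correlation_targets=[("L0", "L1", rho_f, rho_m)],
            seed=seed * 1_000_003 + rep)
        patients, emissions, _ = generate_emissions(config)
        from .factors import FactorScoreMatrix
        scores = FactorScoreMatrix(list(emissions.index),
                                   [f"L{i}" for i in range(4)],
                                   emissions.to_numpy())
        meta = patients.set_index("patient_id").reindex(scores.patient_ids)
        is_case = (meta["cohort_arm"] == "case").to_numpy()
        corr = {}
        for sex in ("F", "M"):
            mask = is_case & (meta["sex"] == sex).to_numpy()
            corr[sex] = phi_matrix(scores, sex, patient_mask=mask)
        from .sexdiff import fdr_mask
        masked = fdr_mask(corr["F"], corr["M"], q=q)
        i = masked.factor_ids.index("L0")
        j = masked.factor_ids.index("L1")
        if masked.difference[i, j] != 0:
            detected += 1
    return detected / n_reps


def type_i_error_simulation(
    n_reps: int = 2000,
    seed: int = 0,
    n_per_sex: int = 200,
    prevalence: float = 0.35,
    alpha: float = 0.05,
) -> float:
    """Rejection rate of the unadjusted two-sided difference test under the
    null: binaries thresholded from independent normal latents (r = 0)."""
    rng = np.random.default_rng(seed)
    thr = stats.norm.ppf(prevalence)
    rejections = 0
    for _ in range(n_reps):
        xf = (rng.standard_normal((n_per_sex, 2)) < thr).astype(float)
        xm = (rng.standard_normal((n_per_sex, 2)) < thr).astype(float)
        r_f = float(np.corrcoef(xf, rowvar=False)[0, 1])
        r_m = float(np.corrcoef(xm, rowvar=False)[0, 1])
        if z_difference(r_f, n_per_sex, r_m, n_per_sex).p < alpha:
            rejections += 1
    return rejections / n_reps
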