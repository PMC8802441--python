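import numpy as np
import pandas as pd
import pytest

from codefactors.cohort import CodeMatrix, EventWindow, PairIndex, binarize_codes
from codefactors.synthetic import (
    FactorBlueprint,
    SimulationConfig,
    WindowShape,
    generate_cohort,
    generate_emissions,
)


def make_blueprints(n_factors=4, codes_per_factor=8, p_ref=None, target_or=2.0,
                    q_on=None, q_bg=0.02):
    """Planted factor blocks with graded strengths.

    Block strengths (q_on) and baseline activation (p_ref) are graded
    across factors by default: equal-strength blocks make the leading PCA
    eigenvalues degenerate, and then no unrotated loading basis can
    separate them.
    """
    letters = "ABCDEFGH"
    if q_on is None:
        q_on = [max(0.35, 0.95 - 0.15 * i) for i in range(n_factors)]
    if p_ref is None:
        p_ref = [min(0.4, 0.10 + 0.05 * i) for i in range(n_factors)]
    q_on = [q_on] * n_factors if np.isscalar(q_on) else list(q_on)
    p_ref = [p_ref] * n_factors if np.isscalar(p_ref) else list(p_ref)
    return [
        FactorBlueprint(
            factor_id=f"L{i}",
            code_ids=tuple(f"{letters[i]}{j:02d}" for j in range(codes_per_factor)),
            p_ref=p_ref[i], target_or=target_or, q_on=q_on[i], q_bg=q_bg)
        for i in range(n_factors)
    ]


def emissions_matrix(patients: pd.DataFrame, emissions: pd.DataFrame) -> CodeMatrix:
    """CodeMatrix straight from the generator's code-level output."""
    return CodeMatrix(list(emissions.index), list(emissions.columns),
                      emissions.to_numpy())


@pytest.fixture(scope="session")
def small_cohort():
    """A 300-pair cohort with 4 planted factors and 30 noise codes."""
    config = SimulationConfig(
        n_pairs_by_sex={"F": 150, "M": 150},
        blueprints=make_blueprints(),
        n_noise_codes=30,
        noise_prevalence=0.05,
        correlation_targets=[("L0", "L1", 0.5, 0.1)],
        window_shape=WindowShape.with_stationary_point(
            peak_height=2.0, days=30, baseline_rate=0.03, span=90),
        seed=42,
    )
    patients, visits, truth = generate_cohort(config)
    return config, patients, visits, truth


@pytest.fixture(scope="session")
def small_matrix(small_cohort):
    config, patients, visits, truth = small_cohort
    matrix = binarize_codes(visits, patients, EventWindow(30, 30))
    pairs = PairIndex.from_patients(patients, matrix)
    return matrix, pairs
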