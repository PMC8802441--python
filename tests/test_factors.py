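import numpy as np
import pytest

from codefactors.cohort import CodeMatrix, PairIndex
from codefactors.factors import (
    FactorModel,
    choose_n_factors,
    define_factors,
    fit_pca_factors,
    score_patients,
)
from codefactors.synthetic import SimulationConfig, generate_emissions

from conftest import emissions_matrix, make_blueprints


def matrix_from(values, codes=None):
    values = np.asarray(values, dtype=np.uint8)
    codes = codes or [f"C{j:02d}" for j in range(values.shape[1])]
    return CodeMatrix([f"p{i}" for i in range(values.shape[0])], codes, values)


@pytest.fixture(scope="module")
def planted():
    config = SimulationConfig(n_pairs_by_sex={"F": 1250, "M": 1250},
                              blueprints=make_blueprints(4, 8, q_bg=0.02),
                              seed=23)
    patients, emissions, truth = generate_emissions(config)
    return emissions_matrix(patients, emissions), truth, patients


class TestFitPcaFactors:
    def test_independent_codes_unit_eigenvalues(self):
        rng = np.random.default_rng(0)
        m = matrix_from(rng.random((20000, 6)) < 0.3)
        model = fit_pca_factors(m)
        assert np.all(np.abs(model.eigenvalues - 1.0) < 0.1)

    def test_two_perfect_blocks(self):
        # all four (a, b) patterns equally often -> sample corr(a, b) is 0
        a = np.repeat([0, 0, 1, 1], 50).astype(np.uint8)
        b = np.repeat([0, 1, 0, 1], 50).astype(np.uint8)
        m = matrix_from(np.column_stack([a, a, a, b, b, b]))
        model = fit_pca_factors(m)
        assert model.eigenvalues[:2] == pytest.approx([3.0, 3.0], abs=1e-8)
        assert model.eigenvalues[2:] == pytest.approx([0.0] * 4, abs=1e-8)
        # block-structured loadings: each of the top-2 factors loads one block
        top = np.abs(model.loadings[:, :2]) > 0.5
        blocks = {tuple(top[:, j]) for j in range(2)}
        assert blocks == {(True, True, True, False, False, False),
                          (False, False, False, True, True, True)}

    def test_column_sumsq_equals_eigenvalue(self, planted):
        matrix, truth, _ = planted
        model = fit_pca_factors(matrix.restrict(sorted(truth.signal_code_ids)))
        sumsq = (model.loadings ** 2).sum(axis=0)
        assert sumsq == pytest.approx(model.eigenvalues, abs=1e-8)

    def test_eigenvalues_sum_to_code_count(self, planted):
        matrix, truth, _ = planted
        codes = sorted(truth.signal_code_ids)
        model = fit_pca_factors(matrix.restrict(codes))
        assert model.eigenvalues.sum() == pytest.approx(len(codes), abs=1e-6)

    def test_reconstruction_identity(self):
        rng = np.random.default_rng(2)
        m = matrix_from(rng.random((300, 5)) < 0.4)
        model = fit_pca_factors(m)
        corr = np.corrcoef(m.values.astype(float), rowvar=False)
        assert np.allclose(model.loadings @ model.loadings.T, corr, atol=1e-6)

    def test_sign_convention(self):
        rng = np.random.default_rng(3)
        m = matrix_from(rng.random((300, 5)) < 0.4)
        model = fit_pca_factors(m)
        for j in range(model.loadings.shape[1]):
            col = model.loadings[:, j]
            assert col[np.argmax(np.abs(col))] >= 0

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(4)
        values = (rng.random((400, 6)) < 0.3).astype(np.uint8)
        m1 = matrix_from(values)
        perm = rng.permutation(values.shape[0])
        m2 = matrix_from(values[perm])
        l1 = fit_pca_factors(m1).loadings
        l2 = fit_pca_factors(m2).loadings
        assert np.allclose(np.abs(l1), np.abs(l2), atol=1e-8)

    def test_zero_variance_named(self):
        values = np.ones((50, 2), dtype=np.uint8)
        values[:, 1] = np.arange(50) % 2
        with pytest.raises(ValueError, match="C00"):
            fit_pca_factors(matrix_from(values))

    def test_needs_two_codes(self):
        with pytest.raises(ValueError):
            fit_pca_factors(matrix_from(np.array([[1], [0]])))


def model_with_eigenvalues(eigs):
    eigs = np.asarray(eigs, dtype=float)
    k = eigs.size
    loadings = np.eye(k) * np.sqrt(eigs)
    return FactorModel(code_ids=[f"C{j}" for j in range(k)], eigenvalues=eigs,
                       loadings=loadings,
                       cumulative_variance=np.cumsum(eigs) / eigs.sum())


class TestChooseNFactors:
    def test_kaiser(self):
        n, report = choose_n_factors(model_with_eigenvalues([3, 2, 0.5, 0.3, 0.2]),
                                     criteria=("kaiser",))
        assert report["kaiser"] == 2
        assert n == 2

    def test_scree_breakpoint(self):
        n, report = choose_n_factors(model_with_eigenvalues([5, 1.2, 1.1, 0.4, 0.3]),
                                     criteria=("scree_breakpoint",))
        assert report["scree_breakpoint"] == 1

    def test_cumulative_variance(self):
        n, report = choose_n_factors(model_with_eigenvalues([3, 2, 0.5, 0.3, 0.2]),
                                     criteria=("cumulative_variance",),
                                     params={"variance_target": 0.8})
        assert report["cumulative_variance"] == 2

    def test_median_combiner_rounds_up(self):
        model = model_with_eigenvalues([5, 1.2, 1.1, 0.4, 0.3])
        n, report = choose_n_factors(model, criteria=("kaiser", "scree_breakpoint"))
        assert report == {"kaiser": 3, "scree_breakpoint": 1}
        assert n == 2  # median of (3, 1)

    def test_auc_loop_requires_pairs(self):
        with pytest.raises(ValueError, match="pair data"):
            choose_n_factors(model_with_eigenvalues([2, 1]), criteria=("auc_loop",))

    def test_unknown_criterion(self):
        with pytest.raises(ValueError):
            choose_n_factors(model_with_eigenvalues([2, 1]), criteria=("magic",))

    def test_planted_four_factors_recovered(self, planted):
        matrix, truth, patients = planted
        sub = matrix.restrict(sorted(truth.signal_code_ids))
        model = fit_pca_factors(sub)
        pairs = PairIndex.from_patients(patients, matrix)
        n, report = choose_n_factors(
            model,
            criteria=("kaiser", "scree_breakpoint", "cumulative_variance", "auc_loop"),
            params={"variance_target": 0.45, "matrix": sub, "pairs": pairs,
                    "max_k": 8})
        assert report["scree_breakpoint"] == 4
        assert report["auc_loop"] == 4
        assert n == 4


class TestDefineFactors:
    def test_multi_membership(self):
        model = FactorModel(code_ids=["A01", "B02"],
                            eigenvalues=np.array([1.2, 0.8]),
                            loadings=np.array([[0.5, 0.25], [0.1, 0.9]]),
                            cumulative_variance=np.array([0.6, 1.0]))
        definitions, unassigned = define_factors(model, 2, cutoff=0.2)
        assert {"A01"} <= definitions[0].code_ids
        assert definitions[1].code_ids == {"A01", "B02"}
        assert unassigned == []

    def test_below_cutoff_unassigned(self):
        model = FactorModel(code_ids=["A01", "B02"],
                            eigenvalues=np.array([1.0, 1.0]),
                            loadings=np.array([[0.15, 0.1], [0.9, 0.05]]),
                            cumulative_variance=np.array([0.5, 1.0]))
        definitions, unassigned = define_factors(model, 2, cutoff=0.2)
        assert unassigned == ["A01"]

    def test_cutoff_range(self):
        model = model_with_eigenvalues([2, 1])
        with pytest.raises(ValueError):
            define_factors(model, 1, cutoff=1.5)

    def test_too_many_factors(self):
        with pytest.raises(ValueError):
            define_factors(model_with_eigenvalues([2, 1]), 5)

    def test_planted_blocks_recovered(self, planted):
        matrix, truth, _ = planted
        model = fit_pca_factors(matrix.restrict(sorted(truth.signal_code_ids)))
        definitions, _ = define_factors(model, 4, cutoff=0.2)
        true_blocks = {}
        for code, fid in truth.code_to_factor.items():
            true_blocks.setdefault(fid, set()).add(code)
        recovered = [d.code_ids for d in definitions]
        for block in true_blocks.values():
            assert any(block == set(r) for r in recovered), block


class TestScorePatients:
    def test_any_of_rule(self):
        m = matrix_from(np.array([[1, 0, 0], [0, 0, 0]]), ["A01", "B02", "C03"])
        from codefactors.factors import FactorDefinition
        d = FactorDefinition("F1", "f", frozenset({"A01", "B02"}), 0.2)
        scores = score_patients(m, [d])
        assert scores.column("F1").tolist() == [1, 0]

    def test_unknown_code_errors(self):
        m = matrix_from(np.array([[1], [0]]), ["A01"])
        from codefactors.factors import FactorDefinition
        d = FactorDefinition("F1", "f", frozenset({"Z99"}), 0.2)
        with pytest.raises(ValueError, match="Z99"):
            score_patients(m, [d])

    def test_matches_bruteforce_set_loop(self):
        from codefactors.factors import FactorDefinition
        rng = np.random.default_rng(7)
        values = (rng.random((60, 10)) < 0.3).astype(np.uint8)
        codes = [f"C{j:02d}" for j in range(10)]
        m = matrix_from(values, codes)
        defs = [FactorDefinition(f"F{k}", "f",
                                 frozenset(rng.choice(codes, 3, replace=False)), 0.2)
                for k in range(4)]
        scores = score_patients(m, defs)
        for i, pid in enumerate(m.patient_ids):
            patient_codes = {c for c, v in zip(codes, values[i]) if v}
            for d in defs:
                expected = int(bool(patient_codes & d.code_ids))
                assert scores.values[i, scores.factor_ids.index(d.factor_id)] == expected


class TestRecoveryInvariant:
    def test_signal_code_assignment_accuracy(self):
        # scaled-down version of the 100-replicate recovery criterion
        # (the full run lives in the acceptance suite)
        correct = total = 0
        for seed in range(10):
            config = SimulationConfig(
                n_pairs_by_sex={"F": 1250, "M": 1250},
                blueprints=make_blueprints(4, 8, q_bg=0.02),
                seed=1000 + seed)
            patients, emissions, truth = generate_emissions(config)
            matrix = emissions_matrix(patients, emissions)
            model = fit_pca_factors(matrix.restrict(sorted(truth.signal_code_ids)))
            definitions, _ = define_factors(model, 4, cutoff=0.2)
            blocks = {}
            for code, fid in truth.code_to_factor.items():
                blocks.setdefault(fid, set()).add(code)
            matched = {}
            for d in definitions:
                best = max(blocks, key=lambda f: len(blocks[f] & d.code_ids))
                matched[d.factor_id] = best
            for code, fid in truth.code_to_factor.items():
                total += 1
                holders = [d for d in definitions if code in d.code_ids]
                if any(matched[d.factor_id] == fid for d in holders):
                    correct += 1
        assert correct / total >= 0.9


class TestVarimax:
    def test_varimax_separates_equal_strength_blocks(self):
        """With equal-strength blocks the unrotated basis mixes them (the
        leading eigenvalues are degenerate); varimax recovers the blocks."""
        config = SimulationConfig(
            n_pairs_by_sex={"F": 1250, "M": 1250},
            blueprints=make_blueprints(4, 8, p_ref=0.15, q_on=0.9, q_bg=0.02),
            seed=77)
        patients, emissions, truth = generate_emissions(config)
        matrix = emissions_matrix(patients, emissions)
        model = fit_pca_factors(matrix, n_factors=4, rotation="varimax")
        definitions, _ = define_factors(model, 4, cutoff=0.2)
        blocks = {}
        for code, fid in truth.code_to_factor.items():
            blocks.setdefault(fid, set()).add(code)
        recovered = [set(d.code_ids) for d in definitions]
        assert sum(1 for b in blocks.values() if b in recovered) == 4

    def test_unknown_rotation_errors(self):
        import numpy as _np
        values = (_np.random.default_rng(0).random((50, 4)) < 0.5).astype(_np.uint8)
        with pytest.raises(ValueError, match="rotation"):
            fit_pca_factors(matrix_from(values), rotation="promax")
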