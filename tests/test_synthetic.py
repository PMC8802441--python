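import time

import numpy as np
import pandas as pd
import pytest

from codefactors import io as cfio
from codefactors.cohort import (
    EventWindow,
    PairIndex,
    binarize_codes,
    detect_event_window,
    validate_patients,
)
from codefactors.screening import by_adjust, discordant_table, mcnemar_test, screen_codes
from codefactors.synthetic import (
    FactorBlueprint,
    SimulationConfig,
    WindowShape,
    case_probability,
    generate_cohort,
    generate_emissions,
    generate_visit_offsets,
    write_fixture,
)

from conftest import emissions_matrix, make_blueprints


class TestBlueprintValidation:
    def test_case_probability_closed_form(self):
        assert case_probability(0.10, 2.0) == pytest.approx(2 / 11)
        assert case_probability(0.3, 1.0) == pytest.approx(0.3)

    @pytest.mark.parametrize("kwargs", [
        dict(p_ref=0.0), dict(p_ref=1.0), dict(target_or=0.0),
        dict(q_on=0.0), dict(q_bg=0.5, q_on=0.5),
    ])
    def test_invalid_blueprint(self, kwargs):
        base = dict(factor_id="F", code_ids=("A00",), p_ref=0.1,
                    target_or=2.0, q_on=0.9, q_bg=0.0)
        base.update(kwargs)
        with pytest.raises(ValueError):
            FactorBlueprint(**base)

    def test_empty_codes_rejected(self):
        with pytest.raises(ValueError):
            FactorBlueprint("F", (), 0.1, 2.0, 0.9, 0.0)

    def test_overlapping_blueprints_rejected(self):
        bps = [FactorBlueprint("F1", ("A00",), 0.1, 2.0, 0.9, 0.0),
               FactorBlueprint("F2", ("A00",), 0.1, 2.0, 0.9, 0.0)]
        with pytest.raises(ValueError, match="A00"):
            SimulationConfig(n_pairs_by_sex={"F": 5}, blueprints=bps)

    def test_unknown_correlation_target_rejected(self):
        bps = [FactorBlueprint("F1", ("A00",), 0.1, 2.0, 0.9, 0.0)]
        with pytest.raises(ValueError, match="unknown factors"):
            SimulationConfig(n_pairs_by_sex={"F": 5}, blueprints=bps,
                             correlation_targets=[("F1", "NOPE", 0.5, 0.5)])

    def test_infeasible_correlation_named(self):
        bps = make_blueprints(3, codes_per_factor=1)
        targets = [("L0", "L1", 0.9, 0.9), ("L1", "L2", 0.9, 0.9),
                   ("L0", "L2", -0.9, -0.9)]
        with pytest.raises(ValueError, match="L0"):
            generate_emissions(SimulationConfig(
                n_pairs_by_sex={"F": 10}, blueprints=bps,
                correlation_targets=targets))


class TestGenerateCohort:
    def test_same_seed_byte_identical(self, small_cohort):
        config, patients, visits, _ = small_cohort
        p2, v2, _ = generate_cohort(config)
        assert patients.to_csv(index=False) == p2.to_csv(index=False)
        assert visits.to_csv(index=False) == v2.to_csv(index=False)

    def test_matched_design_holds(self, small_cohort):
        _, patients, _, _ = small_cohort
        validate_patients(patients)

    def test_null_config_prevalences_balance(self):
        config = SimulationConfig(
            n_pairs_by_sex={"F": 2000, "M": 2000},
            blueprints=[FactorBlueprint("F1", ("A00", "A01"), 0.2, 1.0, 0.9, 0.02)],
            n_noise_codes=20, noise_prevalence=0.1, seed=9)
        patients, emissions, truth = generate_emissions(config)
        is_case = patients["cohort_arm"].to_numpy() == "case"
        case_prev = emissions.loc[patients.loc[is_case, "patient_id"]].mean()
        ref_prev = emissions.loc[patients.loc[~is_case, "patient_id"]].mean()
        # all ORs are 1 -> equal prevalence in expectation (3 MC SEs)
        se = np.sqrt(ref_prev * (1 - ref_prev) * 2 / 4000)
        assert np.all(np.abs(case_prev - ref_prev) < 3.5 * se + 1e-9)

    def test_reference_marginal_prevalence(self):
        config = SimulationConfig(
            n_pairs_by_sex={"F": 4000, "M": 4000},
            blueprints=[FactorBlueprint("F1", ("A00",), 0.15, 2.0, 0.9, 0.02)],
            seed=5)
        patients, emissions, _ = generate_emissions(config)
        refs = patients.loc[patients["cohort_arm"] == "reference", "patient_id"]
        prev = emissions.loc[refs, "A00"].mean()
        expected = 0.15 * 0.9 + 0.85 * 0.02
        se = np.sqrt(expected * (1 - expected) / 8000)
        assert abs(prev - expected) < 3 * se

    def test_latent_correlations_hit_targets(self):
        config = SimulationConfig(
            n_pairs_by_sex={"F": 5000, "M": 5000},
            blueprints=make_blueprints(3, codes_per_factor=2),
            correlation_targets=[("L0", "L1", 0.6, 0.1)], seed=17)
        patients, _, truth = generate_emissions(config)
        is_case = (patients["cohort_arm"] == "case").to_numpy()
        for sex, target in (("F", 0.6), ("M", 0.1)):
            mask = is_case & (patients["sex"] == sex).to_numpy()
            lat = truth.latents.loc[patients.loc[mask, "patient_id"]]
            achieved = np.corrcoef(lat["L0"], lat["L1"])[0, 1]
            assert abs(achieved - target) < 0.05

    def test_emissions_equal_binarized_cohort(self, small_cohort):
        # visit synthesis is lossless: binarizing the generated visits over
        # the planted window recovers exactly the emitted signal/noise codes
        config, patients, visits, truth = small_cohort
        _, emissions, _ = generate_emissions(config)
        matrix = binarize_codes(visits, patients, EventWindow(30, 30))
        sub = matrix.restrict(list(emissions.columns))
        frame = sub.to_frame().loc[emissions.index]
        assert np.array_equal(frame.to_numpy(), emissions.to_numpy())

    def test_cases_carry_case_code_on_index_date(self, small_cohort):
        config, patients, visits, _ = small_cohort
        cases = patients[patients["cohort_arm"] == "case"]
        case_visits = visits[visits["code"] == config.case_code]
        merged = case_visits.merge(cases, on="patient_id")
        assert set(cases["patient_id"]) == set(case_visits["patient_id"])
        assert (merged["visit_date"] == merged["index_date"]).all()


class TestVisitOffsets:
    def test_flat_shape_uniform(self):
        shape = WindowShape(peak_height=0.0, decay_rate=0.0, baseline_rate=1.0, span=50)
        offsets = generate_visit_offsets(60000, shape, seed=0)
        counts = np.bincount(offsets + 50, minlength=101)
        expected = 60000 / 101
        assert np.all(np.abs(counts - expected) < 5 * np.sqrt(expected))
        w = detect_event_window(dict(enumerate(counts.tolist(), start=-50)),
                                tolerance_k=6.0, min_stable_run=10)
        assert w.days_before <= 3 and w.days_after <= 3

    def test_baseline_reached_at_30(self):
        shape = WindowShape.with_stationary_point(0.5, days=30, baseline_rate=0.05, span=90)
        offsets = generate_visit_offsets(50000, shape, seed=1)
        counts = np.bincount(offsets + 90, minlength=181)
        rate = shape.rate(np.arange(-90, 91))
        expected = 50000 * rate / rate.sum()
        for day in (-30, 30):
            e = expected[day + 90]
            assert abs(counts[day + 90] - e) < 3 * np.sqrt(e)

    def test_peak_recovered_by_detector(self):
        shape = WindowShape.with_stationary_point(0.9, days=30, baseline_rate=0.09, span=90)
        offsets = generate_visit_offsets(120000, shape, seed=2)
        vals, counts = np.unique(offsets, return_counts=True)
        w = detect_event_window(dict(zip(vals.tolist(), counts.tolist())),
                                tolerance_k=6.0, min_stable_run=10)
        assert (w.days_before, w.days_after) == (30, 30)

    def test_mode_at_zero(self):
        shape = WindowShape.with_stationary_point(2.0, days=30, baseline_rate=0.05, span=90)
        offsets = generate_visit_offsets(50000, shape, seed=3)
        vals, counts = np.unique(offsets, return_counts=True)
        assert abs(vals[np.argmax(counts)]) <= 1

    def test_nonpositive_baseline_errors(self):
        with pytest.raises(ValueError):
            WindowShape(baseline_rate=0.0)

    def test_detector_recovery_rate(self):
        # >= 95% of seeded replicates recover the stationary offsets within
        # +/- 2 days at peak ~10x baseline
        shape = WindowShape.with_stationary_point(0.9, days=30, baseline_rate=0.09, span=90)
        ok = 0
        reps = 60
        for seed in range(reps):
            offsets = generate_visit_offsets(100000, shape, seed=seed)
            vals, counts = np.unique(offsets, return_counts=True)
            w = detect_event_window(dict(zip(vals.tolist(), counts.tolist())),
                                    tolerance_k=6.0, min_stable_run=10)
            if abs(w.days_before - 30) <= 2 and abs(w.days_after - 30) <= 2:
                ok += 1
        assert ok / reps >= 0.95


class TestFixtureIO:
    def test_round_trip(self, small_cohort, tmp_path):
        _, patients, visits, truth = small_cohort
        paths = write_fixture(patients, visits, truth, tmp_path / "fx")
        p = cfio.read_patients(paths["patients"])
        v = cfio.read_visits(paths["visits"])
        t = cfio.read_ground_truth(paths["ground_truth"])
        pd.testing.assert_frame_equal(
            p[["patient_id", "pair_id", "cohort_arm", "sex", "index_date"]],
            patients[["patient_id", "pair_id", "cohort_arm", "sex", "index_date"]])
        pd.testing.assert_frame_equal(v, visits[["patient_id", "visit_date", "code"]])
        assert t.signal_code_ids == truth.signal_code_ids
        assert t.code_to_factor == truth.code_to_factor
        assert t.factor_or == truth.factor_or
        assert t.pair_rho_by_sex == truth.pair_rho_by_sex

    def test_ground_truth_lists_every_blueprint_code(self, small_cohort, tmp_path):
        config, patients, visits, truth = small_cohort
        paths = write_fixture(patients, visits, truth, tmp_path / "fx")
        t = cfio.read_ground_truth(paths["ground_truth"])
        for bp in config.blueprints:
            assert set(bp.code_ids) <= t.signal_code_ids

    def test_200_pair_fixture_screens_under_5s(self, tmp_path):
        start = time.time()
        config = SimulationConfig(n_pairs_by_sex={"F": 100, "M": 100},
                                  blueprints=make_blueprints(2),
                                  n_noise_codes=20, seed=1)
        patients, visits, truth = generate_cohort(config)
        paths = write_fixture(patients, visits, truth, tmp_path / "fx")
        patients = cfio.read_patients(paths["patients"])
        visits = cfio.read_visits(paths["visits"])
        matrix = binarize_codes(visits, patients, EventWindow(30, 30))
        pairs = PairIndex.from_patients(patients, matrix)
        half = len(pairs) // 2
        train = PairIndex(pairs.pair_ids[:half], pairs.case_rows[:half],
                          pairs.ref_rows[:half])
        val = PairIndex(pairs.pair_ids[half:], pairs.case_rows[half:],
                        pairs.ref_rows[half:])
        screen_codes(matrix, matrix, train, val)
        assert time.time() - start < 5.0


class TestNullScreeningFdr:
    def test_empirical_fdr_small_null_config(self):
        """Single-stage screening on all-null cohorts keeps the empirical
        false-discovery proportion at or below the nominal level."""
        fdps = []
        for seed in range(120):
            config = SimulationConfig(n_pairs_by_sex={"F": 150, "M": 150},
                                      n_noise_codes=60, noise_prevalence=0.08,
                                      seed=seed)
            patients, emissions, truth = generate_emissions(config)
            matrix = emissions_matrix(patients, emissions)
            pairs = PairIndex.from_patients(patients, matrix)
            tab = discordant_table(matrix, pairs)
            from codefactors.screening import DiscordantCounts
            ps = [mcnemar_test(DiscordantCounts(code, int(b), int(c), len(pairs))).p_value
                  for code, b, c in zip(tab["code"], tab["b"], tab["c"])]
            out = by_adjust(ps, q=0.05, ids=list(tab["code"]))
            # every code is null: FDP is 1 whenever anything is rejected
            fdps.append(1.0 if out.k > 0 else 0.0)
        assert float(np.mean(fdps)) <= 0.055
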