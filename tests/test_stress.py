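import dataclasses

import numpy as np
import pytest

from hrvstress import (EXERCISE_TABLE, MATRIX_A, MATRIX_B1, MATRIX_B2,
                       MATRIX_B3, VIDEO_TABLE, HRVParameterVector, InputError,
                       JudgmentMatrix, NormalizationBounds, WeightSet,
                       consistency_ratio, criterion_scores, default_weights,
                       geometric_mean_vector, priority_vector, score_table,
                       stress_change, stress_index)

ALL_MATRICES = [MATRIX_A, MATRIX_B1, MATRIX_B2, MATRIX_B3]

MIN_STRESS = HRVParameterVector(lf_hf=0, tp=0, sdnn=200, pnn50=60, hr=1e-9,
                                hle=0, hrd=0.4, vai=10)
MAX_STRESS = HRVParameterVector(lf_hf=15, tp=9000, sdnn=0, pnn50=0, hr=100,
                                hle=10, hrd=0, vai=0)


class TestJudgmentMatrix:
    def test_non_reciprocal_rejected(self):
        with pytest.raises(InputError):
            JudgmentMatrix(np.array([[1.0, 2.0], [0.4, 1.0]]))

    def test_non_positive_rejected(self):
        with pytest.raises(InputError):
            JudgmentMatrix(np.array([[1.0, -2.0], [-0.5, 1.0]]))

    def test_diagonal_must_be_one(self):
        with pytest.raises(InputError):
            JudgmentMatrix(np.array([[2.0, 1.0], [1.0, 1.0]]))


class TestPriorityVector:
    def test_2x2_closed_form(self):
        w = priority_vector(MATRIX_B1)
        np.testing.assert_allclose(w, [0.75, 0.25], atol=1e-9)

    def test_consistent_matrix_proportional_to_columns(self):
        w = priority_vector(MATRIX_B2)
        np.testing.assert_allclose(w, [3 / 7, 3 / 7, 1 / 7], atol=1e-9)

    def test_criterion_and_b3_weights_match_eigen_oracle(self):
        # oracle: dominant eigenvector from the full eigendecomposition
        for m, expect in [(MATRIX_A, (0.674, 0.226, 0.101)),
                          (MATRIX_B3, (0.625, 0.238, 0.137))]:
            vals, vecs = np.linalg.eig(m.entries)
            lead = np.real(vecs[:, np.argmax(np.real(vals))])
            lead = np.abs(lead) / np.abs(lead).sum()
            w = priority_vector(m)
            np.testing.assert_allclose(w, lead, atol=1e-9)
            np.testing.assert_allclose(w, expect, atol=1e-3)

    def test_consistent_matrix_reproduces_entry_ratios(self):
        w = priority_vector(MATRIX_B2)
        for i in range(3):
            for j in range(3):
                assert MATRIX_B2.entries[i, j] == pytest.approx(w[i] / w[j], abs=1e-9)

    def test_eigen_and_geometric_mean_agree_to_3_decimals(self):
        for m in ALL_MATRICES:
            np.testing.assert_allclose(priority_vector(m),
                                       geometric_mean_vector(m), atol=5e-4)


class TestConsistency:
    def test_b2_exactly_consistent(self):
        lam, ci, cr = consistency_ratio(MATRIX_B2)
        assert lam == pytest.approx(3.0, abs=1e-9)
        assert cr == pytest.approx(0.0, abs=1e-9)

    def test_criterion_matrix_near_threshold(self):
        lam, _, cr = consistency_ratio(MATRIX_A)
        assert lam == pytest.approx(3.086, abs=2e-3)
        assert cr == pytest.approx(0.074, abs=2e-3)

    def test_b3_consistency(self):
        _, _, cr = consistency_ratio(MATRIX_B3)
        assert cr == pytest.approx(0.016, abs=2e-3)

    def test_all_shipped_matrices_pass_saaty_check(self):
        for m in ALL_MATRICES:
            assert consistency_ratio(m)[2] < 0.1

    def test_2x2_cr_defined_zero(self):
        assert consistency_ratio(MATRIX_B1)[2] == 0.0


class TestCriterionScores:
    def test_worked_example_subject1_before(self):
        p = VIDEO_TABLE[0].params
        z1, z2, z3, _ = criterion_scores(p, default_weights())
        assert z1 == pytest.approx(0.086, abs=2e-3)
        assert z2 == pytest.approx(0.825, abs=2e-3)
        assert z3 == pytest.approx(0.696, abs=2e-3)

    def test_minimal_stress_bounds_zero(self):
        z1, z2, z3, _ = criterion_scores(MIN_STRESS, default_weights())
        assert max(z1, z2, z3) == pytest.approx(0.0, abs=1e-9)

    def test_maximal_stress_bounds_one(self):
        z1, z2, z3, _ = criterion_scores(MAX_STRESS, default_weights())
        for z in (z1, z2, z3):
            assert z == pytest.approx(1.0, abs=1e-9)

    def test_out_of_range_values_are_clamped_and_logged(self):
        p = HRVParameterVector(lf_hf=40, tp=20000, sdnn=300, pnn50=80,
                               hr=140, hle=20, hrd=0.9, vai=20)
        z1, z2, z3, clamped = criterion_scores(p, default_weights())
        assert set(clamped) >= {"lf_hf", "tp", "sdnn", "hr"}
        for z in (z1, z2, z3):
            assert 0.0 <= z <= 1.0


class TestStressIndex:
    def test_bounds_map_to_0_and_100(self):
        assert stress_index(MIN_STRESS).z == pytest.approx(0.0, abs=1e-6)
        assert stress_index(MAX_STRESS).z == pytest.approx(100.0, abs=1e-9)

    def test_video_table_worked_examples(self):
        w = default_weights()
        z_s1_before = stress_index(VIDEO_TABLE[0].params, w).z
        z_s5_before = stress_index(VIDEO_TABLE[8].params, w).z
        z_s5_after = stress_index(VIDEO_TABLE[9].params, w).z
        assert z_s1_before == pytest.approx(31.4, abs=0.3)
        assert z_s5_before == pytest.approx(30.4, abs=0.3)
        assert z_s5_after == pytest.approx(62.9, abs=0.3)

    def test_index_always_in_0_100(self, rng):
        w = default_weights()
        for _ in range(200):
            p = HRVParameterVector(
                lf_hf=rng.uniform(0, 50), tp=rng.uniform(0, 3e4),
                sdnn=rng.uniform(0, 400), pnn50=rng.uniform(0, 100),
                hr=rng.uniform(20, 220), hle=rng.uniform(0, 30),
                hrd=rng.uniform(0, 1), vai=rng.uniform(0, 40))
            assert 0.0 <= stress_index(p, w).z <= 100.0

    def test_monotone_in_each_parameter_within_bounds(self):
        base = dict(lf_hf=5, tp=4000, sdnn=100, pnn50=30, hr=70,
                    hle=5, hrd=0.2, vai=5)
        w = default_weights()
        z0 = stress_index(HRVParameterVector(**base), w).z
        rising = {"lf_hf": 6, "tp": 5000, "hr": 80, "hle": 6}
        falling = {"sdnn": 120, "pnn50": 40, "hrd": 0.3, "vai": 7}
        for k, v in rising.items():
            z = stress_index(HRVParameterVector(**{**base, k: v}), w).z
            assert z > z0, f"{k} should raise the index"
        for k, v in falling.items():
            z = stress_index(HRVParameterVector(**{**base, k: v}), w).z
            assert z < z0, f"{k} should lower the index"

    def test_weights_recomputed_not_hardcoded(self):
        # perturbing a judgment consistently changes the resulting index
        m = JudgmentMatrix(np.array([[1.0, 9.0, 9.0],
                                     [1 / 9, 1.0, 1.0],
                                     [1 / 9, 1.0, 1.0]]))
        w_alt = WeightSet(beta=priority_vector(m),
                          lambda1=priority_vector(MATRIX_B1),
                          lambda2=priority_vector(MATRIX_B2),
                          lambda3=priority_vector(MATRIX_B3))
        p = VIDEO_TABLE[0].params
        assert stress_index(p, w_alt).z != pytest.approx(stress_index(p).z, abs=1e-6)


class TestStressChange:
    def test_doubling(self):
        a = stress_index(VIDEO_TABLE[0].params)
        b = dataclasses.replace(a, z=2 * a.z)
        assert stress_change(a, b) == pytest.approx(100.0)
        assert stress_change(a, a) == pytest.approx(0.0)

    def test_zero_baseline_is_nan(self):
        zero = dataclasses.replace(stress_index(MIN_STRESS), z=0.0)
        assert np.isnan(stress_change(zero, stress_index(MAX_STRESS)))

    def test_video_table_max_change(self):
        res = score_table(VIDEO_TABLE)
        assert res["max_change"] == pytest.approx(106.7, rel=0.03)

    def test_every_pair_increases_after_stressor(self):
        for table in (EXERCISE_TABLE, VIDEO_TABLE):
            res = score_table(table)
            assert all(c > 0 for c in res["changes"].values())

    def test_mean_relaxed_state(self):
        res = score_table(VIDEO_TABLE)
        assert res["mean_before"] == pytest.approx(31.4, abs=0.5)
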