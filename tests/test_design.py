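import numpy as np
import pytest

from megp import (
    TrialData,
    build_incidence,
    gxe_env_specific_structures,
    gxe_single_structure,
    intercept_structure,
    main_effect_structure,
    to_wide,
)
from megp.kernels import KernelMatrix


def brute_force_structures(T, K):
    """Entry-by-entry reference construction of every covariance pattern."""
    N = T.n_records
    lines = T.line_index
    envs = T.env_index
    Cg = np.empty((N, N))
    Cge = np.empty((N, N))
    Cl = np.empty((N, N))
    for a in range(N):
        for b in range(N):
            k = K.K[lines[a], lines[b]]
            Cg[a, b] = k
            Cge[a, b] = k if envs[a] == envs[b] else 0.0
            Cl[a, b] = 1.0 if lines[a] == lines[b] else 0.0
    return Cg, Cge, Cl


class TestTrialData:
    def test_duplicate_cell_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            TrialData([("A", "E1", 1.0), ("A", "E1", 2.0)])

    def test_canonical_env_major_ordering(self):
        T = TrialData([("B", "E2", 1.0), ("A", "E1", 2.0), ("A", "E2", 3.0)])
        assert list(T.df["env"]) == ["E1", "E2", "E2"]
        assert list(T.df["line"]) == ["A", "A", "B"]

    def test_explicit_env_order_respected(self):
        T = TrialData([("A", "X", 1.0), ("A", "Y", 2.0)], env_order=["Y", "X"])
        assert T.env_ids == ["Y", "X"]
        assert list(T.df["env"]) == ["Y", "X"]


class TestIncidence:
    def test_balanced_counts(self, tiny_trial):
        D = build_incidence(tiny_trial)
        assert D.ZE.shape == (6, 2)
        np.testing.assert_array_equal(D.ZE.sum(axis=0), [3, 3])

    def test_one_hot_rows(self, tiny_trial):
        D = build_incidence(tiny_trial)
        np.testing.assert_array_equal(D.ZE.sum(axis=1), np.ones(6))
        np.testing.assert_array_equal(D.Zg.sum(axis=1), np.ones(6))

    def test_unbalanced_env_counts(self):
        recs = [("A", "E1", 1.0), ("B", "E1", 2.0), ("A", "E2", 3.0)]
        D = build_incidence(TrialData(recs))
        np.testing.assert_array_equal(D.env_counts, [2, 1])


class TestStructures:
    def test_identity_kernel_marks_shared_lines(self, tiny_trial):
        K = KernelMatrix(["A", "B", "C"], np.eye(3))
        C = main_effect_structure(build_incidence(tiny_trial), K).dense()
        T = tiny_trial
        for a in range(T.n_records):
            for b in range(T.n_records):
                expected = 1.0 if T.line_index[a] == T.line_index[b] else 0.0
                assert C[a, b] == pytest.approx(expected)

    def test_balanced_two_env_block_forms(self, tiny_trial):
        rng = np.random.default_rng(2)
        A = rng.normal(size=(3, 5))
        Kd = A @ A.T / 5
        K = KernelMatrix(["A", "B", "C"], Kd)
        D = build_incidence(tiny_trial)
        Cg = main_effect_structure(D, K).dense()
        np.testing.assert_allclose(Cg, np.block([[Kd, Kd], [Kd, Kd]]), atol=1e-10)
        Cge = gxe_single_structure(D, K).dense()
        Z = np.zeros((3, 3))
        np.testing.assert_allclose(Cge, np.block([[Kd, Z], [Z, Kd]]), atol=1e-12)

    def test_structures_match_brute_force_on_unbalanced_trial(self, small_kernel):
        rng = np.random.default_rng(7)
        lines = small_kernel.line_ids
        recs = [
            (s, f"E{j + 1}", float(rng.normal()))
            for j in range(3)
            for s in lines
            if rng.random() < 0.7
        ]
        T = TrialData(recs)
        K = small_kernel.subset(T.line_ids)
        D = build_incidence(T)
        Cg, Cge, Cl = brute_force_structures(T, K)
        np.testing.assert_allclose(main_effect_structure(D, K).dense(), Cg, atol=1e-8)
        np.testing.assert_allclose(gxe_single_structure(D, K).dense(), Cge, atol=1e-10)
        np.testing.assert_allclose(intercept_structure(D).dense(), Cl, atol=1e-10)

    def test_env_specific_structures_partition_single_variance(self, small_kernel):
        rng = np.random.default_rng(8)
        recs = [
            (s, f"E{j + 1}", float(rng.normal()))
            for j in range(5)
            for s in small_kernel.line_ids
            if rng.random() < 0.8
        ]
        T = TrialData(recs)
        K = small_kernel.subset(T.line_ids)
        D = build_incidence(T)
        parts = gxe_env_specific_structures(D, K)
        assert len(parts) == 5
        total = sum(p.dense() for p in parts)
        np.testing.assert_array_equal(total, gxe_single_structure(D, K).dense())
        # each structure lives only in its own diagonal block
        for j, p in enumerate(parts):
            Cj = p.dense()
            outside = ~np.outer(D.env_index == j, D.env_index == j)
            assert np.all(Cj[outside] == 0.0)

    def test_single_env_specific_equals_single_variance(self, small_kernel):
        recs = [(s, "E1", 0.0) for s in small_kernel.line_ids]
        T = TrialData(recs)
        D = build_incidence(T)
        parts = gxe_env_specific_structures(D, small_kernel)
        assert len(parts) == 1
        np.testing.assert_array_equal(parts[0].dense(),
                                      gxe_single_structure(D, small_kernel).dense())

    def test_intercept_block_of_ones_across_envs(self):
        recs = [("A", f"E{j}", float(j)) for j in range(3)] + [("B", "E0", 9.0)]
        D = build_incidence(TrialData(recs))
        C = intercept_structure(D).dense()
        rows_A = np.where(np.array(D.line_ids)[D.line_index] == "A")[0]
        np.testing.assert_array_equal(C[np.ix_(rows_A, rows_A)], np.ones((3, 3)))
        row_B = np.where(np.array(D.line_ids)[D.line_index] == "B")[0]
        assert np.all(C[np.ix_(rows_A, row_B)] == 0.0)

    def test_l_model_record_covariance_adds_intercept_variance(self, small_kernel):
        # two records of line i across environments: sigma2_g*K[i,i] + sigma2_l
        recs = [("L00001", "E1", 0.0), ("L00001", "E2", 0.0), ("L00002", "E1", 0.0),
                ("L00002", "E2", 0.0)]
        T = TrialData(recs)
        K = small_kernel.subset(T.line_ids)
        D = build_incidence(T)
        sg2, sl2 = 0.7, 0.2
        V = sg2 * main_effect_structure(D, K).dense() + sl2 * intercept_structure(D).dense()
        a = 0  # (L00001, E1)
        b = 2  # (L00001, E2) after env-major sort
        assert T.df.iloc[a]["line"] == T.df.iloc[b]["line"] == "L00001"
        assert V[a, b] == pytest.approx(sg2 * K.K[0, 0] + sl2)

    def test_all_structures_numerically_psd(self, small_kernel):
        rng = np.random.default_rng(9)
        recs = [
            (s, f"E{j}", float(rng.normal()))
            for j in range(3)
            for s in small_kernel.line_ids
            if rng.random() < 0.6
        ]
        T = TrialData(recs)
        K = small_kernel.subset(T.line_ids)
        D = build_incidence(T)
        structs = [
            main_effect_structure(D, K),
            gxe_single_structure(D, K),
            intercept_structure(D),
            *gxe_env_specific_structures(D, K),
        ]
        for s in structs:
            w = np.linalg.eigvalsh(s.dense())
            assert w[0] >= -1e-8 * max(w[-1], 1e-12)

    def test_record_permutation_permutes_structures_consistently(self, small_kernel):
        rng = np.random.default_rng(10)
        recs = [
            (s, f"E{j}", float(rng.normal()))
            for j in range(2)
            for s in small_kernel.line_ids
        ]
        T1 = TrialData(recs)
        T2 = TrialData([recs[i] for i in rng.permutation(len(recs))])
        K = small_kernel
        for build in (main_effect_structure, gxe_single_structure):
            C1 = build(build_incidence(T1), K).dense()
            C2 = build(build_incidence(T2), K).dense()
            np.testing.assert_array_equal(C1, C2)  # canonical ordering is shared

    def test_missing_kernel_line_fails_with_names(self, tiny_trial):
        K = KernelMatrix(["A", "B"], np.eye(2))
        with pytest.raises(KeyError, match="C"):
            main_effect_structure(build_incidence(tiny_trial), K)


class TestWide:
    def test_balanced_pivot_dense(self, tiny_trial):
        W = to_wide(tiny_trial)
        assert W.Y.shape == (3, 2)
        assert W.n_missing == 0

    def test_round_trip_identity_on_observed_cells(self, small_kernel):
        rng = np.random.default_rng(11)
        recs = [
            (s, f"E{j}", float(rng.normal()))
            for j in range(3)
            for s in small_kernel.line_ids
            if rng.random() < 0.7
        ]
        T = TrialData(recs)
        T2 = to_wide(T).to_long()
        assert T2.df.equals(T.df)
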