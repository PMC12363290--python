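"""Kernel construction: standardization, G, Gaussian K, pedigree A, hybrid C/P."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hybridgp.relation_kernels import (
    MarkerMatrix,
    PedigreeTable,
    RelationshipKernel,
    align_kernels,
    build_C,
    build_P,
    compute_G,
    compute_KA,
    compute_gaussian_kernel,
    pedigree_to_A,
    squared_distance_matrix,
    standardize_markers,
    validate_kernel,
)
from hybridgp.phenotypes import PhenotypeTable

from conftest import random_psd


# ---------------------------------------------------------------------------
# marker standardization


class TestStandardizeMarkers:
    def test_hand_example_and_idempotence(self):
        mm = MarkerMatrix(ids=["a", "b", "c"], values=[[0.0], [1.0], [2.0]])
        out = standardize_markers(mm)
        np.testing.assert_allclose(out.values[:, 0], [-1.0, 0.0, 1.0], atol=1e-12)
        assert out.standardized
        again = standardize_markers(out)
        np.testing.assert_allclose(again.values, out.values, atol=1e-10)

    def test_columns_centered_and_unit_sample_sd(self, rng):
        mm = MarkerMatrix(
            ids=[f"g{i}" for i in range(30)],
            values=rng.integers(0, 3, size=(30, 15)).astype(float),
        )
        out = standardize_markers(mm)
        np.testing.assert_allclose(out.values.mean(axis=0), 0.0, atol=1e-8)
        np.testing.assert_allclose(out.values.std(axis=0, ddof=1), 1.0, atol=1e-8)

    def test_zero_variance_policy(self):
        mm = MarkerMatrix(
            ids=["a", "b", "c"],
            values=[[2.0, 0.0], [2.0, 1.0], [2.0, 2.0]],
            marker_ids=["const", "ok"],
        )
        with pytest.warns(UserWarning):
            out = standardize_markers(mm, zero_variance_policy="drop")
        assert out.dropped_markers == ["const"]
        assert out.marker_ids == ["ok"]
        with pytest.raises(ValueError, match="zero-variance"):
            standardize_markers(mm, zero_variance_policy="error")

    def test_rejects_missing_values(self):
        with pytest.raises(ValueError, match="missing"):
            MarkerMatrix(ids=["a", "b"], values=[[0.0], [np.nan]])


# ---------------------------------------------------------------------------
# linear genomic relationship


class TestComputeG:
    def test_hand_example(self):
        mm = MarkerMatrix(
            ids=["a", "b"], values=[[1.0], [-1.0]], standardized=True
        )
        G = compute_G(mm)
        np.testing.assert_allclose(G.matrix, [[1, -1], [-1, 1]], atol=1e-12)
        assert G.kind == "G"

    def test_identical_rows_share_relationship(self, rng):
        X = rng.standard_normal((5, 8))
        X[3] = X[1]
        mm = MarkerMatrix(
            ids=list("abcde"), values=X, standardized=True
        )
        G = compute_G(mm).matrix
        assert G[1, 3] == pytest.approx(G[1, 1])
        assert G[1, 3] == pytest.approx(G[3, 3])

    def test_column_accumulation_oracle_and_psd(self, rng):
        mm = standardize_markers(
            MarkerMatrix(
                ids=[f"g{i}" for i in range(20)],
                values=rng.integers(0, 3, size=(20, 12)).astype(float),
            )
        )
        G = compute_G(mm).matrix
        acc = np.zeros((20, 20))
        for j in range(mm.p):
            acc += np.outer(mm.values[:, j], mm.values[:, j])
        np.testing.assert_allclose(G, acc / mm.p, atol=1e-10)
        assert np.linalg.eigvalsh(G)[0] >= -1e-8

    def test_requires_standardized_input(self):
        mm = MarkerMatrix(ids=["a", "b"], values=[[0.0], [2.0]])
        with pytest.raises(ValueError, match="standardized"):
            compute_G(mm)


# ---------------------------------------------------------------------------
# Gaussian kernel


class TestGaussianKernel:
    def test_worked_example(self):
        mm = MarkerMatrix(ids=["a", "b", "c"], values=[[0, 0], [1, 0], [1, 1]])
        K = compute_gaussian_kernel(mm)
        e1, e2 = np.exp(-1.0), np.exp(-2.0)
        expected = [[1, e1, e2], [e1, 1, e1], [e2, e1, 1]]
        np.testing.assert_allclose(K.matrix, expected, rtol=0, atol=1e-15)
        assert K.bandwidth_info == pytest.approx(1.0)

    def test_squared_distances(self):
        mm = MarkerMatrix(ids=["a", "b"], values=[[0, 0], [1, 1]])
        D = squared_distance_matrix(mm)
        assert D[0, 1] == pytest.approx(2.0)
        assert D[0, 0] == 0.0 and D[1, 1] == 0.0
        np.testing.assert_array_equal(D, D.T)

    def test_unit_diagonal_and_duplicate_rows(self, rng):
        X = rng.standard_normal((8, 5))
        X[4] = X[2]
        K = compute_gaussian_kernel(MarkerMatrix(ids=list("abcdefgh"), values=X))
        np.testing.assert_array_equal(np.diag(K.matrix), 1.0)
        assert K.matrix[2, 4] == pytest.approx(1.0)
        assert ((K.matrix > 0) & (K.matrix <= 1)).all()

    def test_row_permutation_permutes_kernel(self, rng):
        X = rng.standard_normal((10, 6))
        ids = [f"g{i}" for i in range(10)]
        K = compute_gaussian_kernel(MarkerMatrix(ids=ids, values=X)).matrix
        perm = rng.permutation(10)
        Kp = compute_gaussian_kernel(
            MarkerMatrix(ids=[ids[i] for i in perm], values=X[perm])
        ).matrix
        np.testing.assert_allclose(Kp, K[np.ix_(perm, perm)], atol=1e-12)

    def test_degenerate_inputs(self):
        mm = MarkerMatrix(ids=["a", "b"], values=[[1, 1], [1, 1]])
        with pytest.raises(ValueError, match="identical"):
            compute_gaussian_kernel(mm)
        good = MarkerMatrix(ids=["a", "b"], values=[[0, 0], [1, 1]])
        with pytest.raises(ValueError, match="bandwidth_scale"):
            compute_gaussian_kernel(good, bandwidth_scale=0.0)


# ---------------------------------------------------------------------------
# pedigree A


def _oracle_A(pedigree: PedigreeTable) -> np.ndarray:
    """Independent oracle: A = T D T' (parent-averaging decomposition)."""
    ids = pedigree.ids
    n = len(ids)
    pos = {g: i for i, g in enumerate(ids)}
    P = np.zeros((n, n))
    for i, (_, p1, p2) in enumerate(pedigree.records):
        for p in (p1, p2):
            if p is not None:
                P[i, pos[p]] += 0.5
    T = np.linalg.inv(np.eye(n) - P)
    # mendelian sampling variances need parental diagonals -> recurse in order
    d = np.zeros(n)
    A = np.zeros((n, n))
    for i, (_, p1, p2) in enumerate(pedigree.records):
        if p1 is not None and p2 is not None:
            d[i] = 1.0 - 0.25 * A[pos[p1], pos[p1]] - 0.25 * A[pos[p2], pos[p2]]
        elif p1 is not None or p2 is not None:
            par = pos[p1 if p1 is not None else p2]
            d[i] = 1.0 - 0.25 * A[par, par]
        else:
            d[i] = 1.0
        A[: i + 1, : i + 1] = (T[: i + 1, : i + 1] * d[: i + 1]) @ T[: i + 1, : i + 1].T
    return (T * d) @ T.T


class TestPedigreeToA:
    def test_founders_give_identity(self):
        ped = PedigreeTable([("a", None, None), ("b", None, None)])
        np.testing.assert_array_equal(pedigree_to_A(ped).matrix, np.eye(2))

    def test_full_sibs(self):
        ped = PedigreeTable(
            [("f1", None, None), ("f2", None, None), ("s1", "f1", "f2"), ("s2", "f1", "f2")]
        )
        A = pedigree_to_A(ped).matrix
        i, j = ped.ids.index("s1"), ped.ids.index("s2")
        assert A[i, j] == pytest.approx(0.5)
        np.testing.assert_array_equal(np.diag(A), 1.0)

    def test_selfing_inflates_diagonal(self):
        ped = PedigreeTable([("f", None, None), ("o", "f", "f")])
        A = pedigree_to_A(ped).matrix
        assert A[ped.ids.index("o"), ped.ids.index("o")] == pytest.approx(1.5)

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=30, deadline=None)
    def test_matches_decomposition_oracle_on_small_pedigrees(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 7))
        records = []
        for i in range(n):
            if i < 2 or rng.random() < 0.3:
                records.append((f"i{i}", None, None))
            else:
                p1, p2 = rng.integers(0, i, size=2)
                records.append((f"i{i}", f"i{p1}", f"i{p2}"))
        ped = PedigreeTable(records)
        np.testing.assert_allclose(
            pedigree_to_A(ped).matrix, _oracle_A(ped), atol=1e-10
        )

    def test_rejects_cycles_and_unknown_parents(self):
        with pytest.raises(ValueError, match="cyclic"):
            PedigreeTable([("a", "b", None), ("b", "a", None)])
        with pytest.raises(ValueError, match="unknown parent"):
            PedigreeTable([("a", "ghost", None)])


# ---------------------------------------------------------------------------
# hybrid kernels C and P


class TestHybridKernels:
    def test_ka_hand_example(self):
        K = RelationshipKernel(ids=["a", "b"], matrix=[[1, 0.5], [0.5, 1]], kind="K")
        A = RelationshipKernel(ids=["a", "b"], matrix=[[1, 0.25], [0.25, 1]], kind="A")
        KA = compute_KA(K, A)
        np.testing.assert_allclose(KA, [[1.125, 0.75], [0.75, 1.125]], atol=1e-15)
        C = build_C(KA, ids=K.ids)
        P = build_P(KA, ids=K.ids)
        np.testing.assert_allclose(C.matrix, [[1, 2 / 3], [2 / 3, 1]], atol=1e-12)
        np.testing.assert_allclose(P.matrix, C.matrix, atol=1e-12)
        assert C.scaling_info == pytest.approx(1.125)

    def test_identity_A_returns_K(self, rng):
        M = random_psd(rng, 6)
        np.fill_diagonal(M, 1.0)
        K = RelationshipKernel(ids=[f"g{i}" for i in range(6)], matrix=M, kind="K")
        A = RelationshipKernel(ids=K.ids, matrix=np.eye(6), kind="A")
        KA = compute_KA(K, A)
        np.testing.assert_allclose(build_C(KA).matrix, M, atol=1e-12)
        np.testing.assert_allclose(build_P(KA).matrix, M, atol=1e-12)

    def test_ka_generally_asymmetric(self, rng):
        K = random_psd(rng, 4)
        A = random_psd(rng, 4)
        ids = list("wxyz")
        KA = compute_KA(
            RelationshipKernel(ids=ids, matrix=K, kind="K"),
            RelationshipKernel(ids=ids, matrix=A, kind="A"),
        )
        assert np.max(np.abs(KA - KA.T)) > 1e-8

    def test_id_mismatch_rejected(self, rng):
        K = RelationshipKernel(ids=["a", "b"], matrix=np.eye(2), kind="K")
        A = RelationshipKernel(ids=["b", "a"], matrix=np.eye(2), kind="A")
        with pytest.raises(ValueError, match="align"):
            compute_KA(K, A)

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=60, deadline=None)
    def test_scaling_identity(self, seed):
        """mean(diag(KA)) * (C + P) reconstructs KA + KA' entrywise."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 21))
        KA = random_psd(rng, n) @ random_psd(rng, n)
        C = build_C(KA).matrix
        P = build_P(KA).matrix
        lhs = np.mean(np.diag(KA)) * (C + P)
        np.testing.assert_allclose(lhs, KA + KA.T, atol=1e-10)
        assert np.mean(np.diag(C)) == pytest.approx(1.0, abs=1e-10)
        assert np.mean(np.diag(P)) == pytest.approx(1.0, abs=1e-10)

    def test_lower_triangle_of_KA_is_upper_of_AK(self, rng):
        for _ in range(20):
            K, A = random_psd(rng, 7), random_psd(rng, 7)
            KA, AK = K @ A, A @ K
            np.testing.assert_allclose(
                np.tril(KA, -1), np.triu(AK, 1).T, atol=1e-10
            )

    def test_symmetric_unit_diag_KA_self_consistency(self, rng):
        M = random_psd(rng, 5)
        M = (M + M.T) / 2
        np.fill_diagonal(M, 1.0)
        np.testing.assert_allclose(build_C(M).matrix, M, atol=1e-12)

    def test_degenerate_diagonal_rejected(self):
        with pytest.raises(ValueError, match="diagonal"):
            build_C(np.array([[-1.0, 0.0], [0.0, -1.0]]))


# ---------------------------------------------------------------------------
# validation and alignment


class TestValidateKernel:
    def test_identity_is_clean(self):
        k = RelationshipKernel(ids=["a", "b"], matrix=np.eye(2))
        out, rep = validate_kernel(k)
        assert rep.min_eigenvalue == pytest.approx(1.0)
        assert rep.psd and not rep.repaired

    def test_indefinite_matrix_flagged(self):
        k = RelationshipKernel(ids=["a", "b"], matrix=[[1.0, 2.0], [2.0, 1.0]])
        _, rep = validate_kernel(k)
        assert rep.min_eigenvalue == pytest.approx(-1.0)
        assert not rep.psd

    @pytest.mark.parametrize("mode", ["jitter", "eigen_clip"])
    def test_repair_restores_psd_and_mean_diagonal(self, mode):
        k = RelationshipKernel(ids=["a", "b"], matrix=[[1.0, 2.0], [2.0, 1.0]])
        out, rep = validate_kernel(k, repair=mode)
        assert rep.repaired
        assert np.linalg.eigvalsh(out.matrix)[0] >= -1e-10
        assert np.mean(np.diag(out.matrix)) == pytest.approx(1.0)

    def test_asymmetric_input_rejected(self):
        k = RelationshipKernel.__new__(RelationshipKernel)
        k.ids = ["a", "b"]
        k.matrix = np.array([[1.0, 0.5], [0.2, 1.0]])
        k.kind = "custom"
        with pytest.raises(ValueError, match="asymmetric"):
            validate_kernel(k)


class TestAlignKernels:
    def test_reorder_to_common_ids(self, rng):
        M = random_psd(rng, 4)
        ids = ["a", "b", "c", "d"]
        k1 = RelationshipKernel(ids=ids, matrix=M)
        perm = [2, 0, 3, 1]
        k2 = RelationshipKernel(
            ids=[ids[i] for i in perm], matrix=M[np.ix_(perm, perm)]
        )
        a1, a2 = align_kernels([k1, k2])
        assert a1.ids == a2.ids
        np.testing.assert_allclose(a1.matrix, a2.matrix, atol=1e-12)

    def test_restrict_to_phenotyped_genotypes(self, rng):
        k = RelationshipKernel(ids=list("abcde"), matrix=random_psd(rng, 5))
        ph = PhenotypeTable.from_vector(["a", "c", "e"], [1.0, 2.0, 3.0])
        (ak,), aph = align_kernels([k], ph)
        assert ak.ids == ["a", "c", "e"]
        assert len(aph) == 3

    def test_disjoint_ids_error(self, rng):
        k1 = RelationshipKernel(ids=["a", "b"], matrix=np.eye(2))
        k2 = RelationshipKernel(ids=["c", "d"], matrix=np.eye(2))
        with pytest.raises(ValueError, match="intersection"):
            align_kernels([k1, k2])
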