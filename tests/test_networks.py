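"""Network construction, vectorization and fusion contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import morphnet as mn

finite_vectors = hnp.arrays(
    dtype=float,
    shape=st.integers(2, 40),
    elements=st.floats(-50, 50, allow_nan=False, allow_infinity=False),
)


class TestBuildNetwork:
    def test_small_example(self):
        net = mn.build_network([1.0, 3.0, 6.0])
        assert np.array_equal(net, [[0, 2, 5], [2, 0, 3], [5, 3, 0]])

    def test_constant_vector_gives_zero_matrix(self):
        assert not mn.build_network([4.2] * 7).any()

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_double_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=35)
        net = mn.build_network(a)
        for i in range(35):
            for j in range(35):
                assert net[i, j] == abs(a[i] - a[j])

    @given(finite_vectors, st.floats(-20, 20, allow_nan=False))
    @settings(max_examples=60, deadline=None)
    def test_shift_invariance(self, a, c):
        np.testing.assert_allclose(
            mn.build_network(a + c), mn.build_network(a), atol=1e-9
        )

    @given(finite_vectors, st.floats(-5, 5, allow_nan=False))
    @settings(max_examples=60, deadline=None)
    def test_scale_equivariance(self, a, s):
        np.testing.assert_allclose(
            mn.build_network(s * a), abs(s) * mn.build_network(a), atol=1e-9
        )

    @given(finite_vectors)
    @settings(max_examples=60, deadline=None)
    def test_symmetry_zero_diagonal_nonnegative(self, a):
        net = mn.build_network(a)
        assert np.array_equal(net, net.T)
        assert not np.diag(net).any()
        assert (net >= 0).all()

    def test_nonfinite_input_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            mn.build_network([1.0, np.nan, 2.0])


class TestBuildTensor:
    def test_shapes_m4_r35(self, recovery_cohort):
        cohort, _ = recovery_cohort
        tensor = mn.build_tensor(cohort, 0)
        assert tensor.matrices.shape == (4, 35, 35)

    def test_per_view_equals_build_network(self, small_cohort):
        cohort, _ = small_cohort
        tensor = mn.build_tensor(cohort, 3)
        for m in range(cohort.n_views):
            np.testing.assert_array_equal(
                tensor.matrices[m], mn.build_network(cohort.attributes[3, m])
            )

    def test_invariant_under_per_view_constant_shift(self, small_cohort):
        cohort, _ = small_cohort
        before = mn.build_tensor(cohort, 0).matrices
        cohort2 = mn.CorticalAttributeCohort(
            subject_ids=cohort.subject_ids,
            ages=cohort.ages,
            groups=cohort.groups,
            hemisphere=cohort.hemisphere,
            attributes=cohort.attributes + np.array([7.0, -3.0])[None, :, None],
            view_names=cohort.view_names,
        )
        np.testing.assert_allclose(mn.build_tensor(cohort2, 0).matrices, before, atol=1e-9)


class TestVectorize:
    def test_stated_order_r3(self):
        vec, index_map = mn.vectorize(np.array([[0, 2, 5], [2, 0, 3], [5, 3, 0]], float))
        assert vec.tolist() == [2, 5, 3]
        assert [(i, j) for _, i, j in index_map.entries] == [(2, 1), (3, 1), (3, 2)]

    def test_length_595_for_r35(self):
        vec, _ = mn.vectorize(mn.build_network(np.arange(35.0)))
        assert len(vec) == 35 * 34 // 2 == 595

    @pytest.mark.parametrize("r", [2, 5, 12])
    def test_round_trip(self, r):
        rng = np.random.default_rng(r)
        mat = mn.build_network(rng.normal(size=r))
        vec, _ = mn.vectorize(mat)
        np.testing.assert_array_equal(mn.unvectorize(vec, r), mat)

    def test_asymmetric_rejected(self):
        bad = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="asymmetric"):
            mn.vectorize(bad)

    def test_nonzero_diagonal_rejected(self):
        with pytest.raises(ValueError, match="diagonal"):
            mn.vectorize(np.eye(3))


class TestFusion:
    def test_con_concatenates_in_view_order(self):
        rng = np.random.default_rng(0)
        vecs = [mn.vectorize(mn.build_network(rng.normal(size=35)))[0] for _ in range(4)]
        fused, index_map = mn.fuse_con(vecs, 35)
        assert len(fused) == 4 * 595 == 2380
        for m in range(4):
            np.testing.assert_array_equal(fused[m * 595 : (m + 1) * 595], vecs[m])
            assert index_map[m * 595][0] == m + 1

    def test_con_single_view_is_identity(self):
        v = np.arange(3.0)
        fused, _ = mn.fuse_con([v], 3)
        np.testing.assert_array_equal(fused, v)

    def test_avg_small_example(self):
        fused, _ = mn.fuse_avg([np.array([2.0, 5.0, 3.0]), np.array([4.0, 1.0, 3.0])], 3)
        assert fused.tolist() == [3.0, 3.0, 3.0]

    def test_avg_identical_views_is_identity(self):
        v = np.array([2.0, 5.0, 3.0])
        fused, _ = mn.fuse_avg([v, v, v], 3)
        np.testing.assert_array_equal(fused, v)

    def test_avg_commutes_with_matrix_average(self):
        rng = np.random.default_rng(1)
        mats = [mn.build_network(rng.normal(size=8)) for _ in range(3)]
        via_vectors, _ = mn.fuse_avg([mn.vectorize(m)[0] for m in mats], 8)
        via_matrices, _ = mn.vectorize(np.mean(mats, axis=0))
        np.testing.assert_allclose(via_vectors, via_matrices, atol=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            mn.fuse_con([np.zeros(3), np.zeros(4)], 3)
        with pytest.raises(ValueError, match="length"):
            mn.fuse_avg([np.zeros(3), np.zeros(4)], 3)


class TestCohortFeatures:
    def test_dimensionality_contract(self, recovery_cohort):
        cohort, _ = recovery_cohort
        assert mn.cohort_features(cohort, "view2").n_features == 595
        assert mn.cohort_features(cohort, "avg").n_features == 595
        assert mn.cohort_features(cohort, "con").n_features == 2380

    def test_single_view_slices_con(self, small_cohort):
        cohort, _ = small_cohort
        con = mn.cohort_features(cohort, "con")
        view2 = mn.cohort_features(cohort, "view2")
        f = cohort.n_rois * (cohort.n_rois - 1) // 2
        np.testing.assert_array_equal(con.values[:, f : 2 * f], view2.values)

    def test_unknown_fusion_rejected(self, small_cohort):
        cohort, _ = small_cohort
        with pytest.raises(ValueError, match="fusion"):
            mn.cohort_features(cohort, "median")
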