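"""RFE ranking, relevance aggregation and top-K edge extraction."""

import numpy as np
import pytest

import morphnet as mn


def _random_xy(n=30, f=12, seed=0):
    rng = np.random.default_rng(seed)
    return rng.normal(size=(n, f)), rng.uniform(8, 30, n)


@pytest.fixture(scope="module")
def light_rfe():
    return mn.RFEConfig(scorer="rf", scorer_forest=mn.RFConfig(n_trees=25), seed=0)


class TestRfeRank:
    def test_single_feature(self, light_rfe):
        X, y = _random_xy(f=1)
        assert mn.rfe_rank(X, y, light_rfe).tolist() == [1]

    @pytest.mark.parametrize("scorer", ["rf", "svr"])
    @pytest.mark.parametrize("seed", [0, 1])
    def test_permutation_of_1_to_f(self, scorer, seed):
        X, y = _random_xy(f=17, seed=seed)
        cfg = mn.RFEConfig(
            scorer=scorer, scorer_forest=mn.RFConfig(n_trees=25), seed=seed
        )
        ranks = mn.rfe_rank(X, y, cfg)
        assert sorted(ranks.tolist()) == list(range(1, 18))

    @pytest.mark.parametrize("scorer", ["rf", "svr"])
    def test_planted_signal_recovered(self, scorer):
        # 5 informative of 50 features with a linear age signal
        rng = np.random.default_rng(42)
        n, f = 120, 50
        y = rng.uniform(8, 30, n)
        X = rng.normal(size=(n, f))
        informative = [3, 11, 24, 37, 49]
        for col in informative:
            X[:, col] = y * 0.5 + rng.normal(0, 1.0, n)
        cfg = mn.RFEConfig(
            scorer=scorer, scorer_forest=mn.RFConfig(n_trees=50), seed=0
        )
        ranks = mn.rfe_rank(X, y, cfg)
        in_top5 = sum(ranks[c] <= 5 for c in informative)
        assert in_top5 >= 4

    def test_deterministic_given_seed(self, light_rfe):
        X, y = _random_xy()
        np.testing.assert_array_equal(
            mn.rfe_rank(X, y, light_rfe), mn.rfe_rank(X, y, light_rfe)
        )

    def test_constant_target_rejected(self, light_rfe):
        X, _ = _random_xy()
        with pytest.raises(ValueError, match="constant target"):
            mn.rfe_rank(X, np.full(X.shape[0], 20.0), light_rfe)

    def test_empty_feature_set_rejected(self, light_rfe):
        with pytest.raises(ValueError, match="empty feature"):
            mn.rfe_rank(np.empty((10, 0)), np.arange(10.0), light_rfe)

    def test_batch_rule_defaults(self):
        cfg = mn.RFEConfig()
        assert cfg.batch_size(2380) == 50
        assert cfg.batch_size(501) == 50
        assert cfg.batch_size(500) == 50  # 10% of 500
        assert cfg.batch_size(30) == 3
        assert cfg.batch_size(5) == 1  # min 1


class TestSelectTop:
    def test_identity_when_k_equals_f(self):
        X, y = _random_xy()
        ranks = np.arange(1, X.shape[1] + 1)
        reduced, _ = mn.select_top(X, ranks, X.shape[1])
        np.testing.assert_array_equal(reduced, X)

    def test_k1_returns_rank1_column(self):
        X, _ = _random_xy()
        rng = np.random.default_rng(5)
        ranks = rng.permutation(np.arange(1, X.shape[1] + 1))
        reduced, _ = mn.select_top(X, ranks, 1)
        np.testing.assert_array_equal(reduced[:, 0], X[:, np.argmin(ranks)])

    def test_matches_argsort_oracle(self):
        X, _ = _random_xy(f=20, seed=3)
        rng = np.random.default_rng(7)
        ranks = rng.permutation(np.arange(1, 21))
        k = 8
        reduced, _ = mn.select_top(X, ranks, k)
        expected_cols = sorted(np.argsort(ranks)[:k])
        np.testing.assert_array_equal(reduced, X[:, expected_cols])

    def test_k_out_of_range(self):
        X, _ = _random_xy()
        with pytest.raises(ValueError, match="out of range"):
            mn.select_top(X, np.arange(1, X.shape[1] + 1), 0)


class TestRelevance:
    def test_mean_of_fold_ranks(self):
        index_map = mn.FeatureIndexMap.single_view(3)
        folds = [np.array([1, 2, 3]), np.array([1, 3, 2]), np.array([3, 1, 2])]
        table = mn.relevance_scores(folds, index_map)
        np.testing.assert_allclose(table.mean_rank, [5 / 3, 2.0, 7 / 3])

    def test_single_fold_equals_that_fold(self):
        index_map = mn.FeatureIndexMap.single_view(3)
        ranks = np.array([2, 1, 3])
        table = mn.relevance_scores([ranks], index_map)
        np.testing.assert_array_equal(table.mean_rank, ranks)

    def test_matches_brute_force_mean(self):
        rng = np.random.default_rng(11)
        f = 10
        index_map = mn.FeatureIndexMap.single_view(5)
        folds = [rng.permutation(np.arange(1, f + 1)) for _ in range(4)]
        table = mn.relevance_scores(folds, index_map)
        for feat in range(f):
            assert table.mean_rank[feat] == pytest.approx(
                sum(fold[feat] for fold in folds) / 4
            )

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(13)
        f = 10
        index_map = mn.FeatureIndexMap.single_view(5)
        folds = [rng.permutation(np.arange(1, f + 1)) for _ in range(3)]
        perm = rng.permutation(f)
        permuted = mn.relevance_scores([fold[perm] for fold in folds], index_map)
        original = mn.relevance_scores(folds, index_map)
        np.testing.assert_array_equal(permuted.mean_rank, original.mean_rank[perm])

    def test_mismatched_f_rejected(self):
        index_map = mn.FeatureIndexMap.single_view(3)
        with pytest.raises(ValueError):
            mn.relevance_scores([np.array([1, 2, 3, 4])], index_map)


class TestTopKEdges:
    @pytest.fixture()
    def table(self):
        index_map = mn.FeatureIndexMap.concatenated(4, 2)  # 2 views x 6 edges
        rng = np.random.default_rng(17)
        folds = [rng.permutation(np.arange(1, 13)) for _ in range(3)]
        return mn.relevance_scores(folds, index_map)

    def test_edges_carry_view_provenance(self, table):
        edges = mn.top_k_edges(table, 5)
        assert len(edges) == 5
        assert all(view in (1, 2) for view, *_ in edges)
        assert [rank for *_, rank in edges] == [1, 2, 3, 4, 5]

    def test_k_equals_f_returns_sorted_table(self, table):
        edges = mn.top_k_edges(table, 12)
        scores = [score for *_, score, _ in edges]
        assert scores == sorted(scores)

    def test_matches_sorted_table_prefix(self, table):
        edges = mn.top_k_edges(table, 4)
        expected = table.sorted_indices()[:4]
        assert [table.index_map[f] for f in expected] == [
            (v, i, j) for v, i, j, _, _ in edges
        ]

    def test_k_out_of_range(self, table):
        with pytest.raises(ValueError, match="out of range"):
            mn.top_k_edges(table, 13)
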