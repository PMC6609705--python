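"""Regression forest, metrics and the cross-validated evaluation."""

import numpy as np
import pytest

import morphnet as mn
from morphnet.pipeline import DEFAULT_TREE_GRID
from tests.conftest import fast_pipeline_config, small_params


def _xy(n=60, f=8, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, f))
    y = 18 + 4 * X[:, 0] + rng.normal(0, 1, n)
    return X, np.clip(y, 5, 35)


class TestTrainForest:
    def test_constant_target_predicts_constant(self):
        X, _ = _xy()
        forest = mn.train_forest(X, np.full(X.shape[0], 21.0), mn.RFConfig(n_trees=20))
        np.testing.assert_allclose(mn.predict_age(forest, X), 21.0)

    def test_predictions_bounded_by_training_range(self):
        X, y = _xy(seed=1)
        forest = mn.train_forest(X, y, mn.RFConfig(n_trees=40))
        rng = np.random.default_rng(2)
        pred = mn.predict_age(forest, rng.normal(0, 5, size=(50, X.shape[1])))
        assert pred.min() >= y.min() and pred.max() <= y.max()

    def test_training_mae_below_noise_sd(self, small_cohort):
        # with planted linear signal, in-sample error beats the noise floor
        cohort, truth = small_cohort
        feats = mn.cohort_features(cohort, "view1")
        forest = mn.train_forest(feats.values, cohort.ages, mn.RFConfig())
        train_mae = mn.mae(mn.predict_age(forest, feats.values), cohort.ages)
        noise_sd_in_age_units = 0.10 / 0.06  # attribute noise over strongest slope
        assert train_mae < noise_sd_in_age_units

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            mn.train_forest(np.ones((1, 3)), np.array([10.0]))

    def test_mtry_rounds_up(self):
        assert mn.RFConfig().mtry(595) == 199  # ceil(595/3)
        assert mn.RFConfig().mtry(2) == 1
        assert mn.RFConfig(predictors_per_split=1.0).mtry(7) == 7

    def test_protocol_defaults(self):
        cfg = mn.RFConfig()
        assert cfg.n_trees == 150
        assert cfg.min_leaf_size == 5
        assert cfg.predictors_per_split == pytest.approx(1 / 3)
        assert DEFAULT_TREE_GRID == tuple(range(20, 201, 20))


class TestPredictAge:
    def test_single_tree_equals_leaf_value(self):
        X, y = _xy(n=40)
        forest = mn.train_forest(X, y, mn.RFConfig(n_trees=1))
        np.testing.assert_allclose(
            mn.predict_age(forest, X), forest.model.estimators_[0].predict(X)
        )

    def test_duplicated_training_subjects_predicted_near_targets(self):
        # re-presenting training subjects at test time must beat held-out
        # error: the forest memorizes its own subjects to within leaf size
        X, y = _xy(n=120, seed=3)
        forest = mn.train_forest(X[:80], y[:80], mn.RFConfig(n_trees=300))
        train_mae = mn.mae(mn.predict_age(forest, X[:80]), y[:80])
        heldout_mae = mn.mae(mn.predict_age(forest, X[80:]), y[80:])
        assert train_mae < heldout_mae

    def test_prediction_length_and_schema_check(self):
        X, y = _xy()
        forest = mn.train_forest(X, y, mn.RFConfig(n_trees=10))
        assert len(mn.predict_age(forest, X[:7])) == 7
        with pytest.raises(ValueError, match="features"):
            mn.predict_age(forest, X[:, :3])


class TestMetrics:
    def test_perfect_prediction(self):
        y = np.array([10.0, 15.0, 20.0, 25.0])
        r, p = mn.pearson_and_p(y, y)
        assert r == pytest.approx(1.0)
        assert mn.mae(y, y) == 0.0

    def test_perfect_anticorrelation(self):
        y = np.array([10.0, 15.0, 20.0, 25.0])
        r, _ = mn.pearson_and_p(-y, y)
        assert r == pytest.approx(-1.0)

    def test_constant_offset_mae(self):
        y = np.array([10.0, 15.0, 20.0])
        assert mn.mae(y + 2, y) == pytest.approx(2.0)

    def test_matches_closed_form_oracles(self):
        rng = np.random.default_rng(9)
        pred, true = rng.normal(20, 5, 50), rng.normal(20, 5, 50)
        r, p = mn.pearson_and_p(pred, true)
        # direct covariance formula
        pc, tc = pred - pred.mean(), true - true.mean()
        r_oracle = (pc @ tc) / np.sqrt((pc @ pc) * (tc @ tc))
        assert r == pytest.approx(r_oracle, abs=1e-12)
        # p from the exact t transform
        from scipy import stats

        t = r_oracle * np.sqrt(48 / (1 - r_oracle**2))
        p_oracle = 2 * stats.t.sf(abs(t), 48)
        assert p == pytest.approx(p_oracle, rel=1e-10)
        assert mn.mae(pred, true) == pytest.approx(np.abs(pred - true).mean(), abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            mn.pearson_and_p(np.ones(5), np.arange(5.0))

    def test_empty_mae_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            mn.mae(np.array([]), np.array([]))


class TestEvaluateCV:
    def test_partition_property(self, small_cohort):
        cohort, _ = small_cohort
        feats = mn.cohort_features(cohort, "view1")
        res = mn.evaluate_cv(feats, cohort.ages, fast_pipeline_config())
        # every subject in exactly one test fold, predicted once
        assert np.all(res.fold_of_subject >= 0)
        assert np.all(np.isfinite(res.predictions))
        counts = np.bincount(res.fold_of_subject, minlength=5)
        assert counts.sum() == cohort.n_subjects and (counts > 0).all()

    def test_strong_signal_recovered(self, small_cohort):
        cohort, _ = small_cohort
        feats = mn.cohort_features(cohort, "view1")
        res = mn.evaluate_cv(feats, cohort.ages, fast_pipeline_config())
        assert res.pearson_r > 0.7

    def test_deterministic_given_seed(self, small_cohort):
        cohort, _ = small_cohort
        feats = mn.cohort_features(cohort, "view1")
        r1 = mn.evaluate_cv(feats, cohort.ages, fast_pipeline_config(seed=5))
        r2 = mn.evaluate_cv(feats, cohort.ages, fast_pipeline_config(seed=5))
        np.testing.assert_array_equal(r1.predictions, r2.predictions)
        assert r1.pearson_r == r2.pearson_r

    def test_too_few_subjects_rejected(self):
        X = np.ones((3, 4))
        with pytest.raises(ValueError, match="folds"):
            mn.evaluate_cv(X, np.array([10.0, 12.0, 14.0]), fast_pipeline_config())

    def test_nested_grid_choice_recorded(self, small_cohort):
        cohort, _ = small_cohort
        feats = mn.cohort_features(cohort, "view1")
        cfg = fast_pipeline_config(n_features=None, grid=(5, 20))
        res = mn.evaluate_cv(feats, cohort.ages, cfg)
        assert len(res.chosen_features) == 5
        assert all(k in (5, 20) for k in res.chosen_features)


class TestFeatureGrid:
    def test_single_view_grid(self):
        assert mn.feature_grid(595, "view2") == tuple(range(50, 595, 50)) + (595,)
        assert mn.feature_grid(595, "avg")[0] == 50

    def test_con_grid(self):
        grid = mn.feature_grid(2380, "con")
        assert grid[0] == 100 and grid[-1] == 2380
        assert grid[1] - grid[0] == 100

    def test_tiny_f(self):
        assert mn.feature_grid(10, "avg") == (10,)


class TestTreeSweep:
    def test_grid_coverage_and_output(self, small_cohort):
        cohort, _ = small_cohort
        feats = mn.cohort_features(cohort, "view1")
        cfg = fast_pipeline_config(forest=mn.RFConfig(n_trees=10), n_folds=3)
        sweep = mn.tree_sweep(feats, cohort.ages, cfg, n_trees_grid=(20, 40))
        assert sweep["n_trees"].tolist() == [20, 40]
        assert {"pearson_r", "mae", "p_value"} <= set(sweep.columns)
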