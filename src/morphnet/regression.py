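"""Regression random forest for age prediction, plus the evaluation metrics.

The forest follows bagging: each tree is trained on a bootstrap resample of
the training subjects and the forest prediction is the mean of the tree
predictions, so predictions always lie within the training age range.
Defaults mirror the reference protocol: 150 trees, minimum leaf size 5, and
one third of the variables sampled as split candidates (rounded up).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.ensemble import RandomForestRegressor

__all__ = ["RFConfig", "AgeForest", "train_forest", "predict_age", "pearson_and_p", "mae"]


@dataclass(frozen=True)
class RFConfig:
    """Regression-forest hyperparameters.

    Parameters
    ----------
    n_trees
        Number of trees in the ensemble.
    min_leaf_size
        Minimum number of training subjects per leaf.
    predictors_per_split
        Fraction of the F features sampled as candidates at each split;
        the count used is ``ceil(predictors_per_split * F)``.
    seed
        Seed for bootstrap resampling and split sampling.
    """

    n_trees: int = 150
    min_leaf_size: int = 5
    predictors_per_split: float = 1.0 / 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.min_leaf_size < 1:
            raise ValueError("min_leaf_size must be >= 1")
        if not 0.0 < self.predictors_per_split <= 1.0:
            raise ValueError("predictors_per_split must be in (0, 1]")

    def mtry(self, n_features: int) -> int:
        """Split candidates for a given feature count: ``ceil(fraction * F)``."""
        return max(1, math.ceil(self.predictors_per_split * n_features))


@dataclass
class AgeForest:
    """A trained regression forest with its training-age range."""

    model: RandomForestRegressor
    n_features: int
    age_range: tuple[float, float]
    config: RFConfig


def train_forest(X: np.ndarray, y: np.ndarray, config: RFConfig | None = None) -> AgeForest:
    """Fit a regression random forest on subjects ``X`` with ages ``y``."""
    config = config or RFConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (subjects x features)")
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y disagree on the number of subjects")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 training subjects")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in training data")
    model = RandomForestRegressor(
        n_estimators=config.n_trees,
        min_samples_leaf=config.min_leaf_size,
        max_features=config.mtry(X.shape[1]),
        bootstrap=True,
        random_state=config.seed,
        n_jobs=1,
    )
    model.fit(X, y)
    return AgeForest(
        model=model,
        n_features=X.shape[1],
        age_range=(float(np.min(y)), float(np.max(y))),
        config=config,
    )


def predict_age(forest: AgeForest, X: np.ndarray) -> np.ndarray:
    """Predict ages: mean of the per-tree predictions for each subject."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != forest.n_features:
        raise ValueError(
            f"expected {forest.n_features} features, got "
            f"{X.shape[1] if X.ndim == 2 else 'non-2-D input'}"
        )
    return forest.model.predict(X)


def pearson_and_p(pred: np.ndarray, true: np.ndarray) -> tuple[float, float]:
    """Pearson correlation between predicted and true ages with two-sided p.

    The p-value uses the exact t transform ``t = r * sqrt((n-2)/(1-r^2))``
    with ``n - 2`` degrees of freedom.
    """
    pred = np.asarray(pred, dtype=float)
    true = np.asarray(true, dtype=float)
    if pred.shape != true.shape or pred.ndim != 1:
        raise ValueError("pred and true must be 1-D vectors of equal length")
    if pred.size < 3:
        raise ValueError("need at least 3 subjects for a correlation")
    if np.std(pred) == 0 or np.std(true) == 0:
        raise ValueError("correlation undefined for a constant vector")
    res = stats.pearsonr(pred, true)
    return float(res.statistic), float(res.pvalue)


def mae(pred: np.ndarray, true: np.ndarray) -> float:
    """Mean absolute error in years."""
    pred = np.asarray(pred, dtype=float)
    true = np.asarray(true, dtype=float)
    if pred.shape != true.shape:
        raise ValueError("pred and true must have equal length")
    if pred.size == 0:
        raise ValueError("MAE undefined for empty input")
    return float(np.mean(np.abs(pred - true)))
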