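"""Cross-validated age-prediction pipeline: RFE ranking, feature-count
selection, regression forest, pooled out-of-fold metrics.

Every subject is predicted exactly once, by a model whose training folds
never contained that subject.  The number of selected features is chosen by
nested cross-validation inside each training fold by default; a legacy mode
evaluating the feature-count grid on the outer test folds exists for
comparison but leaks test labels into the choice and is off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from .networks import FeatureIndexMap, FeatureMatrix
from .ranking import RFEConfig, RelevanceTable, relevance_scores, rfe_rank, select_top
from .regression import RFConfig, mae, pearson_and_p, predict_age, train_forest

__all__ = ["PipelineConfig", "CVResult", "evaluate_cv", "feature_grid", "tree_sweep",
           "DEFAULT_TREE_GRID"]

#: Tree-count sweep protocol: 20 to 200 trees in increments of 20.
DEFAULT_TREE_GRID: tuple[int, ...] = tuple(range(20, 201, 20))


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end pipeline settings.

    Parameters
    ----------
    rfe
        RFE configuration, or ``None`` to skip feature selection entirely.
    n_features
        Fixed number of selected features per fold.  ``None`` selects the
        count from ``grid`` by nested CV inside each training fold.
    grid
        Candidate feature counts; ``None`` derives the standard grid from
        the fusion mode (start/step 50 for single-view and AVG, 100 for
        CON, up to the full feature count).  Ignored when ``n_features``
        is set or ``rfe`` is ``None``.
    inner_folds
        Folds of the nested grid-selection CV.
    legacy_grid
        Evaluate the grid on the outer test fold instead (leaky; for
        comparison only).
    forest
        Final regression-forest hyperparameters.
    n_folds
        Outer cross-validation folds.
    seed
        Run-level seed; fold splits, RFE and forests derive from it.
    """

    rfe: RFEConfig | None = field(default_factory=RFEConfig)
    n_features: int | None = None
    grid: tuple[int, ...] | None = None
    inner_folds: int = 3
    legacy_grid: bool = False
    forest: RFConfig = field(default_factory=RFConfig)
    n_folds: int = 5
    seed: int = 0


def feature_grid(n_features: int, fusion: str) -> tuple[int, ...]:
    """Standard feature-count grid: {50, 100, ..., F} for single-view/AVG
    fusion, {100, 200, ..., F} for CON."""
    step = 100 if fusion.lower() == "con" else 50
    grid = list(range(step, n_features + 1, step))
    if not grid or grid[-1] != n_features:
        grid.append(n_features)
    return tuple(g for g in grid if 1 <= g <= n_features)


@dataclass
class CVResult:
    """Out-of-fold predictions and pooled metrics of one CV evaluation."""

    subject_ids: list[str] | None
    true_ages: np.ndarray
    predictions: np.ndarray
    fold_of_subject: np.ndarray
    pearson_r: float
    p_value: float
    mae: float
    per_fold: list[dict]
    chosen_features: list[int]
    per_fold_ranks: np.ndarray | None
    index_map: FeatureIndexMap | None

    def relevance(self) -> RelevanceTable:
        """Fold-averaged relevance scores (requires RFE and an index map)."""
        if self.per_fold_ranks is None or self.index_map is None:
            raise ValueError("no per-fold RFE ranks recorded for this result")
        return relevance_scores(self.per_fold_ranks, self.index_map)

    def to_frame(self) -> pd.DataFrame:
        ids = self.subject_ids or [str(i) for i in range(len(self.true_ages))]
        return pd.DataFrame(
            {
                "subject_id": ids,
                "true_age": self.true_ages,
                "predicted_age": self.predictions,
                "fold": self.fold_of_subject,
            }
        )

    def summary(self) -> dict:
        return {
            "pearson_r": self.pearson_r,
            "p_value": self.p_value,
            "mae": self.mae,
            "n_subjects": int(len(self.true_ages)),
            "n_folds": int(len(self.per_fold)),
            "chosen_features": list(self.chosen_features),
        }


def _as_matrix(
    features: FeatureMatrix | np.ndarray,
) -> tuple[np.ndarray, FeatureIndexMap | None, str]:
    if isinstance(features, FeatureMatrix):
        return features.values, features.index_map, features.fusion
    return np.asarray(features, dtype=float), None, "view1"


def _choose_k(
    X_tr: np.ndarray,
    y_tr: np.ndarray,
    ranks: np.ndarray,
    grid: Sequence[int],
    config: PipelineConfig,
    seed: int,
) -> int:
    """Pick the feature count minimizing inner-CV MAE (ties -> smaller k)."""
    if len(grid) == 1:
        return int(grid[0])
    inner = KFold(n_splits=config.inner_folds, shuffle=True, random_state=seed)
    best_k, best_mae = None, np.inf
    for k in grid:
        X_k, _ = select_top(X_tr, ranks, k)
        errs = []
        for tr, te in inner.split(X_k):
            forest = train_forest(
                X_k[tr], y_tr[tr], replace(config.forest, seed=seed)
            )
            errs.append(mae(predict_age(forest, X_k[te]), y_tr[te]))
        m = float(np.mean(errs))
        if m < best_mae:
            best_k, best_mae = int(k), m
    assert best_k is not None
    return best_k


def evaluate_cv(
    features: FeatureMatrix | np.ndarray,
    ages: np.ndarray,
    config: PipelineConfig | None = None,
    subject_ids: list[str] | None = None,
) -> CVResult:
    """Run the full k-fold evaluation of the age-prediction pipeline.

    Per fold: RFE ranks the training portion's features, the feature count
    is chosen (fixed, or by nested CV on the training portion), a regression
    forest is trained on the selected features, and the held-out fold is
    predicted.  Pooled Pearson r / p and MAE are computed once over all
    out-of-fold predictions.
    """
    config = config or PipelineConfig()
    X, index_map, fusion = _as_matrix(features)
    y = np.asarray(ages, dtype=float)
    n = X.shape[0]
    if n != y.shape[0]:
        raise ValueError("features and ages disagree on N")
    if n < config.n_folds:
        raise ValueError(f"cannot split {n} subjects into {config.n_folds} folds")

    rng = np.random.default_rng(config.seed)
    splitter = KFold(n_splits=config.n_folds, shuffle=True, random_state=config.seed)
    predictions = np.full(n, np.nan)
    fold_of_subject = np.full(n, -1, dtype=int)
    per_fold: list[dict] = []
    chosen: list[int] = []
    fold_ranks: list[np.ndarray] = []

    grid: Sequence[int] | None = None
    if config.rfe is not None and config.n_features is None:
        grid = config.grid or feature_grid(X.shape[1], fusion)

    for fold_no, (tr, te) in enumerate(splitter.split(X)):
        assert not np.intersect1d(tr, te).size  # out-of-fold guarantee
        fold_seed = int(rng.integers(0, 2**31 - 1))
        X_tr, y_tr = X[tr], y[tr]

        if config.rfe is not None:
            ranks = rfe_rank(X_tr, y_tr, replace(config.rfe, seed=fold_seed))
            fold_ranks.append(ranks)
            if config.n_features is not None:
                k = min(int(config.n_features), X.shape[1])
            elif config.legacy_grid:
                k = _legacy_choose_k(X, y, tr, te, ranks, grid, config, fold_seed)
            else:
                k = _choose_k(X_tr, y_tr, ranks, grid, config, fold_seed)
            X_fit, _ = select_top(X_tr, ranks, k)
            X_te, _ = select_top(X[te], ranks, k)
        else:
            k = X.shape[1]
            X_fit, X_te = X_tr, X[te]

        forest = train_forest(X_fit, y_tr, replace(config.forest, seed=fold_seed))
        pred = predict_age(forest, X_te)
        predictions[te] = pred
        fold_of_subject[te] = fold_no
        chosen.append(k)
        fold_metrics = {"fold": fold_no, "n_test": int(te.size), "chosen_k": k,
                        "mae": mae(pred, y[te])}
        if te.size >= 3 and np.std(pred) > 0 and np.std(y[te]) > 0:
            r_f, p_f = pearson_and_p(pred, y[te])
            fold_metrics.update(pearson_r=r_f, p_value=p_f)
        per_fold.append(fold_metrics)

    assert np.all(fold_of_subject >= 0)  # every subject predicted exactly once
    r, p = pearson_and_p(predictions, y)
    return CVResult(
        subject_ids=subject_ids,
        true_ages=y,
        predictions=predictions,
        fold_of_subject=fold_of_subject,
        pearson_r=r,
        p_value=p,
        mae=mae(predictions, y),
        per_fold=per_fold,
        chosen_features=chosen,
        per_fold_ranks=np.stack(fold_ranks) if fold_ranks else None,
        index_map=index_map,
    )


def _legacy_choose_k(
    X: np.ndarray,
    y: np.ndarray,
    tr: np.ndarray,
    te: np.ndarray,
    ranks: np.ndarray,
    grid: Sequence[int],
    config: PipelineConfig,
    seed: int,
) -> int:
    """Grid evaluated on the outer test fold (uses test labels; comparison
    mode only)."""
    best_k, best_mae = int(grid[0]), np.inf
    for k in grid:
        X_fit, _ = select_top(X[tr], ranks, k)
        X_te, _ = select_top(X[te], ranks, k)
        forest = train_forest(X_fit, y[tr], replace(config.forest, seed=seed))
        m = mae(predict_age(forest, X_te), y[te])
        if m < best_mae:
            best_k, best_mae = int(k), m
    return best_k


def tree_sweep(
    features: FeatureMatrix | np.ndarray,
    ages: np.ndarray,
    config: PipelineConfig | None = None,
    n_trees_grid: Sequence[int] = DEFAULT_TREE_GRID,
) -> pd.DataFrame:
    """Re-run the CV evaluation across a grid of forest sizes.

    The default grid is 20 to 200 trees in steps of 20, the protocol used to
    settle on the 150-tree default.  Returns one row per tree count with the
    pooled metrics.
    """
    config = config or PipelineConfig()
    rows = []
    for n_trees in n_trees_grid:
        cfg = replace(config, forest=replace(config.forest, n_trees=int(n_trees)))
        res = evaluate_cv(features, ages, cfg)
        rows.append(
            {"n_trees": int(n_trees), "pearson_r": res.pearson_r,
             "p_value": res.p_value, "mae": res.mae}
        )
    return pd.DataFrame(rows)
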