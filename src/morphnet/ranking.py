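"""Recursive feature elimination, fold-averaged relevance, fingerprint edges.

RFE fits the configured scorer on the surviving features, removes a batch of
the lowest-importance ones, and repeats until every feature has received a
rank (rank 1 = most age-predictive).  Ranks are always a permutation of
``1..F``: within an eliminated batch, features are ordered by their
importance at elimination time, ties broken by ascending feature index.

Averaging a feature's rank across cross-validation folds gives its
*relevance score*; the lowest-scoring features are the connectional
fingerprints of brain age.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.svm import SVR

from .networks import FeatureIndexMap
from .regression import RFConfig

__all__ = [
    "RFEConfig",
    "RelevanceTable",
    "rfe_rank",
    "select_top",
    "relevance_scores",
    "top_k_edges",
]


@dataclass(frozen=True)
class RFEConfig:
    """RFE settings.

    Parameters
    ----------
    scorer
        ``"rf"`` scores features by impurity importance of a regression
        random forest (configured by ``scorer_forest``); ``"svr"`` by the
        squared coefficients of a linear-kernel support-vector regressor.
    batch
        Features eliminated per iteration.  ``None`` applies the default
        rule: 50 while more than 500 features remain, otherwise 10% of the
        remaining features (at least 1).  A float in (0, 1) eliminates that
        fraction of the remaining features; an int eliminates a fixed count.
    scorer_forest
        Forest hyperparameters for the ``"rf"`` scorer.
    svr_c, svr_epsilon
        Linear-SVR hyperparameters for the ``"svr"`` scorer.
    seed
        Base seed; each elimination round derives its own scorer seed.
    """

    scorer: str = "rf"
    batch: int | float | None = None
    scorer_forest: RFConfig = field(default_factory=RFConfig)
    svr_c: float = 1.0
    svr_epsilon: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scorer not in ("rf", "svr"):
            raise ValueError(f"unknown scorer {self.scorer!r}")
        if isinstance(self.batch, float) and not 0.0 < self.batch < 1.0:
            raise ValueError("fractional batch must be in (0, 1)")
        if isinstance(self.batch, int) and self.batch < 1:
            raise ValueError("integer batch must be >= 1")

    def batch_size(self, n_remaining: int) -> int:
        if self.batch is None:
            if n_remaining > 500:
                return 50
            return max(1, int(round(0.10 * n_remaining)))
        if isinstance(self.batch, float):
            return max(1, int(round(self.batch * n_remaining)))
        return self.batch


def _importances(
    X: np.ndarray, y: np.ndarray, config: RFEConfig, round_seed: int
) -> np.ndarray:
    if config.scorer == "rf":
        fc = config.scorer_forest
        model = RandomForestRegressor(
            n_estimators=fc.n_trees,
            min_samples_leaf=fc.min_leaf_size,
            max_features=fc.mtry(X.shape[1]),
            bootstrap=True,
            random_state=round_seed,
            n_jobs=1,
        )
        model.fit(X, y)
        return model.feature_importances_
    model = SVR(kernel="linear", C=config.svr_c, epsilon=config.svr_epsilon)
    model.fit(X, y)
    return np.ravel(np.asarray(model.coef_)) ** 2


def rfe_rank(X: np.ndarray, y: np.ndarray, config: RFEConfig | None = None) -> np.ndarray:
    """Rank all features by recursive elimination.

    Returns
    -------
    numpy.ndarray
        Length-``F`` integer array; a permutation of ``1..F`` with rank 1 the
        most relevant feature.  Deterministic for a fixed config seed.
    """
    config = config or RFEConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be N x F with matching y")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 training subjects")
    if X.shape[1] == 0:
        raise ValueError("cannot rank an empty feature set")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in input")
    if np.std(y) == 0:
        raise ValueError("constant target: feature relevance is undefined")

    n_features = X.shape[1]
    remaining = np.arange(n_features)
    ranks = np.zeros(n_features, dtype=int)
    worst_rank = n_features  # next rank handed out, counting down from F
    rng = np.random.default_rng(config.seed)
    while remaining.size:
        round_seed = int(rng.integers(0, 2**31 - 1))
        imp = _importances(X[:, remaining], y, config, round_seed)
        k = min(config.batch_size(remaining.size), remaining.size)
        # Worst first: ascending importance, ties by ascending feature index.
        order = np.lexsort((remaining, imp))
        if remaining.size > k:
            drop_local = order[:k]
        else:
            drop_local = order  # final round ranks everything left
        for local in drop_local:
            ranks[remaining[local]] = worst_rank
            worst_rank -= 1
        keep = np.ones(remaining.size, dtype=bool)
        keep[drop_local] = False
        remaining = remaining[keep]
    assert worst_rank == 0
    return ranks


def select_top(
    X: np.ndarray, ranks: np.ndarray, k: int, index_map: FeatureIndexMap | None = None
) -> tuple[np.ndarray, FeatureIndexMap | None]:
    """Keep the columns ranked ``<= k``, preserving original column order."""
    X = np.asarray(X)
    ranks = np.asarray(ranks)
    if not 1 <= k <= ranks.size:
        raise ValueError(f"k={k} out of range 1..{ranks.size}")
    idx = np.flatnonzero(ranks <= k)
    reduced_map = index_map.subset(idx) if index_map is not None else None
    return X[:, idx], reduced_map


@dataclass
class RelevanceTable:
    """Per-feature fold-averaged RFE ranks.

    ``mean_rank[f]`` is feature ``f``'s rank averaged over CV folds; lower is
    more relevant.  ``per_fold_ranks`` has shape (folds, F).
    """

    mean_rank: np.ndarray
    per_fold_ranks: np.ndarray
    index_map: FeatureIndexMap

    def sorted_indices(self) -> np.ndarray:
        """Feature indices by ascending relevance score, ties by index."""
        return np.argsort(self.mean_rank, kind="stable")


def relevance_scores(
    per_fold_ranks: list[np.ndarray] | np.ndarray, index_map: FeatureIndexMap
) -> RelevanceTable:
    """Average per-fold RFE ranks into a relevance score per feature."""
    ranks = np.asarray(per_fold_ranks, dtype=float)
    if ranks.ndim != 2 or ranks.shape[0] < 1:
        raise ValueError("need a (folds x F) array with at least one fold")
    if ranks.shape[1] != len(index_map):
        raise ValueError(
            f"rank vectors cover {ranks.shape[1]} features but index map has "
            f"{len(index_map)}"
        )
    return RelevanceTable(
        mean_rank=ranks.mean(axis=0),
        per_fold_ranks=ranks,
        index_map=index_map,
    )


def top_k_edges(
    table: RelevanceTable, k: int
) -> list[tuple[int, int, int, float, int]]:
    """The ``k`` most relevant edges, best first.

    Returns tuples ``(view, roi_i, roi_j, relevance_score, rank)`` with
    1-based view/ROI indices, directly serializable by
    :func:`morphnet.io.write_edge_list`.
    """
    n_features = len(table.index_map)
    if not 1 <= k <= n_features:
        raise ValueError(f"k={k} out of range 1..{n_features}")
    order = table.sorted_indices()[:k]
    return [
        (
            table.index_map[f][0],
            table.index_map[f][1],
            table.index_map[f][2],
            float(table.mean_rank[f]),
            rank,
        )
        for rank, f in enumerate(order, start=1)
    ]
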