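"""Comparison estimators: SVR, SVR+RFE, RF without selection, and a
simplified connectome-based predictive model (CPM).

All baselines share the fold splitter and metric conventions of the primary
pipeline, so rows are directly comparable; ``rf_rfe`` *is* the primary
pipeline (same code path, bit-identical results at equal seeds).

The CPM implementation is deliberately simplified: edges are split into
positive and negative sets by the sign of their Pearson correlation with
age at a p-value threshold, summed into two per-subject strength scores,
and a linear model maps the scores to age.  It accepts only matrix-shaped
(single-view or AVG) features — concatenated views do not form an R x R
network, so ``cpm`` with CON fusion is refused.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import KFold
from sklearn.svm import SVR

from .networks import FeatureMatrix
from .pipeline import CVResult, PipelineConfig, _as_matrix, evaluate_cv, feature_grid
from .ranking import RFEConfig, rfe_rank, select_top
from .regression import mae, pearson_and_p

__all__ = ["CPMSummary", "cpm_summarize", "cpm_strengths", "run_baseline", "BASELINE_METHODS"]

logger = logging.getLogger(__name__)

BASELINE_METHODS = ("svr", "svr_rfe", "rf", "rf_rfe", "cpm")


@dataclass
class CPMSummary:
    """Edge sets and per-subject strengths of the simplified CPM."""

    positive_idx: np.ndarray  # feature columns positively correlated with age
    negative_idx: np.ndarray
    threshold_p: float
    correlations: np.ndarray  # per-edge Pearson r with age (NaN if degenerate)


def cpm_summarize(
    train_features: np.ndarray, train_ages: np.ndarray, threshold_p: float = 0.01
) -> CPMSummary:
    """Split edges by the sign of significant edge-age correlations.

    Degenerate (constant) edges are skipped with a log notice.  The positive
    and negative sets are disjoint by construction.
    """
    X = np.asarray(train_features, dtype=float)
    y = np.asarray(train_ages, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 training subjects for correlations")
    n_features = X.shape[1]
    r = np.full(n_features, np.nan)
    p = np.full(n_features, np.nan)
    n_constant = 0
    for f in range(n_features):
        col = X[:, f]
        if np.std(col) == 0:
            n_constant += 1
            continue
        res = stats.pearsonr(col, y)
        r[f], p[f] = res.statistic, res.pvalue
    if n_constant:
        logger.info("CPM: skipped %d constant edge(s)", n_constant)
    keep = np.isfinite(p) & (p < threshold_p)
    return CPMSummary(
        positive_idx=np.flatnonzero(keep & (r > 0)),
        negative_idx=np.flatnonzero(keep & (r < 0)),
        threshold_p=threshold_p,
        correlations=r,
    )


def cpm_strengths(summary: CPMSummary, X: np.ndarray) -> np.ndarray:
    """Per-subject (positive, negative) strength sums, shape (N, 2)."""
    X = np.asarray(X, dtype=float)
    pos = X[:, summary.positive_idx].sum(axis=1)
    neg = X[:, summary.negative_idx].sum(axis=1)
    return np.column_stack([pos, neg])


def _pooled_result(
    y: np.ndarray,
    predictions: np.ndarray,
    fold_of_subject: np.ndarray,
    per_fold: list[dict],
    chosen: list[int],
    subject_ids: list[str] | None,
) -> CVResult:
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
        per_fold_ranks=None,
        index_map=None,
    )


def run_baseline(
    method: str,
    features: FeatureMatrix | np.ndarray,
    ages: np.ndarray,
    config: PipelineConfig | None = None,
    threshold_p: float = 0.01,
    subject_ids: list[str] | None = None,
) -> CVResult:
    """Cross-validated evaluation of one comparison method.

    ``method`` is one of ``svr``, ``svr_rfe``, ``rf``, ``rf_rfe``, ``cpm``.
    ``rf_rfe`` delegates to the primary pipeline; ``rf`` is the same forest
    without feature selection.  ``cpm`` refuses concatenated (CON) features.
    """
    config = config or PipelineConfig()
    method = method.lower()
    if method not in BASELINE_METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {BASELINE_METHODS}")

    X, _, fusion = _as_matrix(features)
    y = np.asarray(ages, dtype=float)

    if method == "rf_rfe":
        return evaluate_cv(features, ages, config, subject_ids=subject_ids)
    if method == "rf":
        return evaluate_cv(
            features, ages, replace(config, rfe=None), subject_ids=subject_ids
        )
    if method == "cpm" and fusion == "con":
        raise ValueError(
            "CPM requires matrix-shaped (single-view or AVG) features; "
            "concatenated views are not an R x R network"
        )

    rng = np.random.default_rng(config.seed)
    splitter = KFold(config.n_folds, shuffle=True, random_state=config.seed)
    predictions = np.full(len(y), np.nan)
    fold_of_subject = np.full(len(y), -1, dtype=int)
    per_fold: list[dict] = []
    chosen: list[int] = []

    for fold_no, (tr, te) in enumerate(splitter.split(X)):
        fold_seed = int(rng.integers(0, 2**31 - 1))
        X_tr, y_tr = X[tr], y[tr]
        if method == "svr":
            model = _svr(config).fit(X_tr, y_tr)
            pred = model.predict(X[te])
            k = X.shape[1]
        elif method == "svr_rfe":
            rfe_cfg = replace(
                config.rfe or RFEConfig(), scorer="svr", seed=fold_seed
            )
            ranks = rfe_rank(X_tr, y_tr, rfe_cfg)
            k = _svr_pick_k(X_tr, y_tr, ranks, config, fold_seed)
            X_fit, _ = select_top(X_tr, ranks, k)
            X_te, _ = select_top(X[te], ranks, k)
            model = _svr(config).fit(X_fit, y_tr)
            pred = model.predict(X_te)
        else:  # cpm
            summary = cpm_summarize(X_tr, y_tr, threshold_p=threshold_p)
            n_edges = summary.positive_idx.size + summary.negative_idx.size
            k = int(n_edges)
            if n_edges == 0:
                pred = np.full(te.size, float(np.mean(y_tr)))
            else:
                model = LinearRegression().fit(cpm_strengths(summary, X_tr), y_tr)
                pred = model.predict(cpm_strengths(summary, X[te]))
        predictions[te] = pred
        fold_of_subject[te] = fold_no
        chosen.append(k)
        per_fold.append(
            {"fold": fold_no, "n_test": int(te.size), "chosen_k": k,
             "mae": mae(pred, y[te])}
        )

    return _pooled_result(y, predictions, fold_of_subject, per_fold, chosen, subject_ids)


def _svr(config: PipelineConfig) -> SVR:
    rfe = config.rfe or RFEConfig()
    return SVR(kernel="linear", C=rfe.svr_c, epsilon=rfe.svr_epsilon)


def _svr_pick_k(
    X_tr: np.ndarray,
    y_tr: np.ndarray,
    ranks: np.ndarray,
    config: PipelineConfig,
    seed: int,
) -> int:
    """Feature count for SVR+RFE by nested CV, mirroring the primary rule."""
    if config.n_features is not None:
        return min(int(config.n_features), X_tr.shape[1])
    grid = config.grid or feature_grid(X_tr.shape[1], "view")
    if len(grid) == 1:
        return int(grid[0])
    inner = KFold(config.inner_folds, shuffle=True, random_state=seed)
    best_k, best_mae = int(grid[0]), np.inf
    for k in grid:
        X_k, _ = select_top(X_tr, ranks, k)
        errs = [
            mae(_svr(config).fit(X_k[i], y_tr[i]).predict(X_k[j]), y_tr[j])
            for i, j in inner.split(X_k)
        ]
        m = float(np.mean(errs))
        if m < best_mae:
            best_k, best_mae = int(k), m
    return best_k
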