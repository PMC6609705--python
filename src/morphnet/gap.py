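"""Healthy-baseline model, morphological brain-age gaps, and gap-augmented
disorder classification.

A model trained only on normal-control (NC) subjects defines what healthy
aging looks like in the network features; applying it to disordered
subjects yields a *morphological brain-age gap* — predicted minus
chronological age — whose absolute value serves as a disorder biomarker.
NC subjects' own gaps are always computed out-of-fold within NC, so the
baseline never predicts a subject it was trained on.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import KFold, StratifiedKFold

from .cohort import GROUP_DISORDERED, GROUP_NC
from .networks import FeatureMatrix
from .pipeline import PipelineConfig, _as_matrix, _choose_k, feature_grid
from .ranking import rfe_rank
from .regression import AgeForest, predict_age, train_forest

__all__ = [
    "AgeGapRecord",
    "HealthyBaseline",
    "GapAnalysis",
    "ClassificationResult",
    "fit_healthy_baseline",
    "compute_gaps",
    "gap_analysis",
    "classify_with_gap",
]


@dataclass(frozen=True)
class AgeGapRecord:
    """One subject's predicted vs chronological age and the gap in years."""

    subject_id: str
    predicted_age: float
    chronological_age: float

    @property
    def signed_gap(self) -> float:
        return self.predicted_age - self.chronological_age

    @property
    def abs_gap(self) -> float:
        return abs(self.signed_gap)


@dataclass
class HealthyBaseline:
    """RFE + forest pipeline fitted on healthy subjects only."""

    forest: AgeForest
    feature_idx: np.ndarray  # columns of the original matrix kept
    n_features_original: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_original:
            raise ValueError(
                f"feature schema mismatch: expected {self.n_features_original} "
                "columns"
            )
        return predict_age(self.forest, X[:, self.feature_idx])


def _fit_pipeline_once(
    X: np.ndarray, y: np.ndarray, config: PipelineConfig, fusion: str, seed: int
) -> HealthyBaseline:
    if config.rfe is not None:
        ranks = rfe_rank(X, y, replace(config.rfe, seed=seed))
        if config.n_features is not None:
            k = min(int(config.n_features), X.shape[1])
        else:
            grid = config.grid or feature_grid(X.shape[1], fusion)
            k = _choose_k(X, y, ranks, grid, config, seed)
        idx = np.flatnonzero(ranks <= k)
    else:
        idx = np.arange(X.shape[1])
    forest = train_forest(X[:, idx], y, replace(config.forest, seed=seed))
    return HealthyBaseline(
        forest=forest, feature_idx=idx, n_features_original=X.shape[1]
    )


def fit_healthy_baseline(
    features: FeatureMatrix | np.ndarray,
    ages: np.ndarray,
    groups: list[str],
    config: PipelineConfig | None = None,
) -> HealthyBaseline:
    """Fit the baseline healthy model on an all-NC cohort.

    Rejects any input containing a non-NC subject: the caller must subset
    explicitly, so a disordered subject can never leak into the baseline.
    """
    config = config or PipelineConfig()
    non_nc = sorted({g for g in groups if g != GROUP_NC})
    if non_nc:
        raise ValueError(
            f"healthy baseline requires NC subjects only; found {non_nc}"
        )
    X, _, fusion = _as_matrix(features)
    y = np.asarray(ages, dtype=float)
    if len(groups) != X.shape[0] or y.shape[0] != X.shape[0]:
        raise ValueError("features, ages and groups disagree on N")
    seed = int(np.random.default_rng(config.seed).integers(0, 2**31 - 1))
    return _fit_pipeline_once(X, y, config, fusion, seed)


def compute_gaps(
    model: HealthyBaseline,
    features: FeatureMatrix | np.ndarray,
    ages: np.ndarray,
    subject_ids: list[str] | None = None,
) -> list[AgeGapRecord]:
    """Predicted-vs-chronological age gap for every subject."""
    X, _, _ = _as_matrix(features)
    y = np.asarray(ages, dtype=float)
    pred = model.predict(X)
    ids = subject_ids or [str(i) for i in range(len(y))]
    return [
        AgeGapRecord(subject_id=s, predicted_age=float(p), chronological_age=float(a))
        for s, p, a in zip(ids, pred, y)
    ]


@dataclass
class GapAnalysis:
    """Per-subject gaps plus the group-level acceleration estimate."""

    records: list[AgeGapRecord]
    groups: list[str]

    def mean_signed_gap(self, group: str) -> float:
        gaps = [r.signed_gap for r, g in zip(self.records, self.groups) if g == group]
        if not gaps:
            raise ValueError(f"no subjects in group {group!r}")
        return float(np.mean(gaps))

    @property
    def group_difference(self) -> float:
        """Mean signed gap of the disordered group minus the NC group's."""
        return self.mean_signed_gap(GROUP_DISORDERED) - self.mean_signed_gap(GROUP_NC)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": [r.subject_id for r in self.records],
                "group": self.groups,
                "chronological_age": [r.chronological_age for r in self.records],
                "predicted_age": [r.predicted_age for r in self.records],
                "signed_gap": [r.signed_gap for r in self.records],
                "abs_gap": [r.abs_gap for r in self.records],
            }
        )


def gap_analysis(
    features: FeatureMatrix | np.ndarray,
    ages: np.ndarray,
    groups: list[str],
    config: PipelineConfig | None = None,
    subject_ids: list[str] | None = None,
    nc_folds: int = 5,
) -> GapAnalysis:
    """Run the healthy-baseline gap protocol on a mixed cohort.

    Disordered subjects are scored by a baseline trained on *all* NC
    subjects.  NC subjects are scored leave-fold-out: NC is split into
    ``nc_folds`` folds and each fold is predicted by a baseline trained on
    the remaining NC subjects, so no NC gap is optimistically near zero by
    memorization.
    """
    config = config or PipelineConfig()
    X, _, fusion = _as_matrix(features)
    y = np.asarray(ages, dtype=float)
    groups = list(groups)
    ids = subject_ids or [str(i) for i in range(len(y))]
    nc_idx = np.array([i for i, g in enumerate(groups) if g == GROUP_NC])
    dis_idx = np.array([i for i, g in enumerate(groups) if g != GROUP_NC])
    if nc_idx.size < nc_folds:
        raise ValueError(f"need at least {nc_folds} NC subjects")

    rng = np.random.default_rng(config.seed)
    pred = np.full(len(y), np.nan)

    # NC: leave-fold-out within NC.
    for tr, te in KFold(nc_folds, shuffle=True, random_state=config.seed).split(nc_idx):
        seed = int(rng.integers(0, 2**31 - 1))
        model = _fit_pipeline_once(X[nc_idx[tr]], y[nc_idx[tr]], config, fusion, seed)
        assert not np.intersect1d(nc_idx[tr], nc_idx[te]).size
        pred[nc_idx[te]] = model.predict(X[nc_idx[te]])

    # Disordered: baseline trained on the full NC group.
    if dis_idx.size:
        seed = int(rng.integers(0, 2**31 - 1))
        model = _fit_pipeline_once(X[nc_idx], y[nc_idx], config, fusion, seed)
        pred[dis_idx] = model.predict(X[dis_idx])

    records = [
        AgeGapRecord(subject_id=s, predicted_age=float(p), chronological_age=float(a))
        for s, p, a in zip(ids, pred, y)
    ]
    return GapAnalysis(records=records, groups=groups)


@dataclass
class ClassificationResult:
    """Gap-augmented NC vs disordered classification under k-fold CV."""

    true_labels: np.ndarray
    predicted_labels: np.ndarray
    fold_of_subject: np.ndarray
    per_fold: list[dict]

    @property
    def accuracy(self) -> float:
        return float(np.mean(self.true_labels == self.predicted_labels))

    @property
    def sensitivity(self) -> float:
        """Disordered recall."""
        pos = self.true_labels == GROUP_DISORDERED
        return float(np.mean(self.predicted_labels[pos] == GROUP_DISORDERED))

    @property
    def specificity(self) -> float:
        """NC recall."""
        neg = self.true_labels == GROUP_NC
        return float(np.mean(self.predicted_labels[neg] == GROUP_NC))

    def summary(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "per_fold": self.per_fold,
        }


def classify_with_gap(
    features: FeatureMatrix | np.ndarray,
    ages: np.ndarray,
    groups: list[str],
    config: PipelineConfig | None = None,
    n_folds: int = 5,
    nc_inner_folds: int = 3,
) -> ClassificationResult:
    """Classify NC vs disordered from network features plus the age gap.

    Stratified ``n_folds`` CV over all subjects.  In each fold a healthy
    baseline is fitted on that fold's NC *training* subjects only; gaps for
    the test subjects and for disordered training subjects come from that
    baseline, while NC training subjects get leave-fold-out gaps within the
    NC training set.  The classifier input is the feature vector augmented
    with the signed and absolute gap, fed to a random-forest classifier
    with the regression defaults.
    """
    config = config or PipelineConfig()
    X, _, fusion = _as_matrix(features)
    y = np.asarray(ages, dtype=float)
    labels = np.asarray(groups, dtype=object)
    classes = set(labels)
    if classes != {GROUP_NC, GROUP_DISORDERED}:
        raise ValueError(
            f"need both NC and DISORDERED subjects, found {sorted(classes)}"
        )

    rng = np.random.default_rng(config.seed)
    splitter = StratifiedKFold(n_folds, shuffle=True, random_state=config.seed)
    predicted = np.empty(len(y), dtype=object)
    fold_of_subject = np.full(len(y), -1, dtype=int)
    per_fold: list[dict] = []

    for fold_no, (tr, te) in enumerate(splitter.split(X, labels)):
        assert not np.intersect1d(tr, te).size
        seed = int(rng.integers(0, 2**31 - 1))
        nc_tr = tr[labels[tr] == GROUP_NC]
        dis_tr = tr[labels[tr] == GROUP_DISORDERED]

        baseline = _fit_pipeline_once(X[nc_tr], y[nc_tr], config, fusion, seed)

        gaps = np.full(len(y), np.nan)
        gaps[te] = baseline.predict(X[te]) - y[te]
        if dis_tr.size:
            gaps[dis_tr] = baseline.predict(X[dis_tr]) - y[dis_tr]
        # NC training gaps: leave-fold-out within the NC training subjects.
        inner = KFold(
            min(nc_inner_folds, nc_tr.size), shuffle=True, random_state=seed
        )
        for itr, ite in inner.split(nc_tr):
            sub = _fit_pipeline_once(X[nc_tr[itr]], y[nc_tr[itr]], config, fusion, seed)
            gaps[nc_tr[ite]] = sub.predict(X[nc_tr[ite]]) - y[nc_tr[ite]]

        def augment(idx: np.ndarray) -> np.ndarray:
            g = gaps[idx]
            return np.column_stack([X[idx], g, np.abs(g)])

        clf = RandomForestClassifier(
            n_estimators=config.forest.n_trees,
            min_samples_leaf=config.forest.min_leaf_size,
            max_features=config.forest.mtry(X.shape[1] + 2),
            random_state=seed,
            n_jobs=1,
        )
        clf.fit(augment(tr), labels[tr].astype(str))
        pred_te = clf.predict(augment(te))
        predicted[te] = pred_te
        fold_of_subject[te] = fold_no
        per_fold.append(
            {
                "fold": fold_no,
                "n_test": int(te.size),
                "accuracy": float(np.mean(pred_te == labels[te].astype(str))),
            }
        )

    assert np.all(fold_of_subject >= 0)
    return ClassificationResult(
        true_labels=labels.astype(str),
        predicted_labels=predicted.astype(str),
        fold_of_subject=fold_of_subject,
        per_fold=per_fold,
    )
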