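"""Shared fixtures.

Heavy cross-validated runs are session-scoped so several tests can assert
against one computation.  Small helper cohorts are built fresh per test.
"""

from __future__ import annotations

import numpy as np
import pytest

import morphnet as mn


def small_params(seed: int = 0, **overrides) -> mn.SyntheticParams:
    """A compact planted-signal cohort for fast unit tests: R=10, M=2,
    N=80, two strong signal ROIs in view 1."""
    n_views, n_rois = 2, 10
    slopes = np.zeros((n_views, n_rois))
    slopes[0, 0] = 0.06
    slopes[0, 5] = -0.06
    baselines = np.full((n_views, n_rois), 2.0)
    baselines[0] += 30.0 * slopes[0]
    defaults = dict(
        n_subjects=80,
        n_rois=n_rois,
        n_views=n_views,
        age_range=(8.0, 30.0),
        slopes=slopes,
        baselines=baselines,
        noise_sd=np.array([0.10, 0.05]),
        seed=seed,
    )
    defaults.update(overrides)
    return mn.SyntheticParams(**defaults)


def fast_pipeline_config(seed: int = 0, **overrides) -> mn.PipelineConfig:
    """Cheap but complete pipeline settings for unit-scale cohorts."""
    defaults = dict(
        rfe=mn.RFEConfig(
            scorer="rf", batch=0.5, scorer_forest=mn.RFConfig(n_trees=25)
        ),
        n_features=10,
        forest=mn.RFConfig(n_trees=60),
        n_folds=5,
        seed=seed,
    )
    defaults.update(overrides)
    return mn.PipelineConfig(**defaults)


@pytest.fixture(scope="session")
def recovery_cohort():
    """The fixed recovery scenario: cohort + ground truth at seed 0."""
    params = mn.default_recovery_scenario(seed=0)
    cohort, truth = mn.generate(params)
    return cohort, truth


@pytest.fixture(scope="session")
def small_cohort():
    params = small_params(seed=1)
    return mn.generate(params)


@pytest.fixture(scope="session")
def recovery_con_result(recovery_cohort):
    """One full 5-fold CON evaluation of the recovery scenario.

    Shared by the ranking-recovery and age-prediction acceptance checks.
    Uses a 50-tree scorer forest for RFE and a coarse feature-count grid to
    keep the run desk-scale; the final regressor keeps the 150-tree default.
    """
    cohort, _ = recovery_cohort
    features = mn.cohort_features(cohort, "con")
    config = mn.PipelineConfig(
        rfe=mn.RFEConfig(scorer="rf", scorer_forest=mn.RFConfig(n_trees=50)),
        grid=(100, 300, 600),
        forest=mn.RFConfig(),
        n_folds=5,
        seed=0,
    )
    result = mn.evaluate_cv(features, cohort.ages, config)
    return features, result
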