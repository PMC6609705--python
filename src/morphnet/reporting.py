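"""Run configuration handling and report generation.

A run is fully described by a YAML (or JSON) config; the resolved config is
written next to the outputs so that config + seed reproduce every artifact
byte-for-byte.  Outputs are plain CSV/JSON: a metrics summary, per-subject
out-of-fold predictions, the fold-averaged relevance table, and one ranked
edge list per requested top-K.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synthetic
from .atlas import ROIAtlas, desikan_killiany, read_atlas
from .baselines import run_baseline
from .cohort import CorticalAttributeCohort
from .gap import classify_with_gap, gap_analysis
from .io import write_cohort, write_edge_list
from .networks import cohort_features
from .pipeline import PipelineConfig, evaluate_cv
from .ranking import RFEConfig, top_k_edges
from .regression import RFConfig

__all__ = ["RunConfig", "load_run_config", "run_pipeline", "run_gap", "run_bench",
           "simulate_to_dir"]

logger = logging.getLogger(__name__)

_SCENARIOS = {
    "default_recovery": synthetic.default_recovery_scenario,
    "accelerated": synthetic.accelerated_scenario,
    "separable": synthetic.separable_scenario,
}


@dataclass
class RunConfig:
    """Resolved settings of one pipeline run."""

    cohort_dir: str | None = None
    scenario: str | None = "default_recovery"
    atlas: str | None = None  # path, or None for the 35-ROI Desikan-Killiany
    fusion: str = "con"
    zscore_views: bool = False
    rfe_scorer: str = "rf"
    rfe_batch: int | float | None = None
    rfe_scorer_trees: int = 150
    n_trees: int = 150
    min_leaf_size: int = 5
    predictors_per_split: float = 1.0 / 3.0
    n_features: int | None = None
    grid: list[int] | None = None
    folds: int = 5
    inner_folds: int = 3
    legacy_grid: bool = False
    seed: int = 0
    k_list: list[int] = field(default_factory=lambda: [5, 10, 15])
    output_dir: str = "morphnet_out"
    log_level: str = "INFO"

    def pipeline_config(self) -> PipelineConfig:
        return PipelineConfig(
            rfe=RFEConfig(
                scorer=self.rfe_scorer,
                batch=self.rfe_batch,
                scorer_forest=RFConfig(
                    n_trees=self.rfe_scorer_trees,
                    min_leaf_size=self.min_leaf_size,
                    predictors_per_split=self.predictors_per_split,
                ),
                seed=self.seed,
            ),
            n_features=self.n_features,
            grid=tuple(self.grid) if self.grid else None,
            inner_folds=self.inner_folds,
            legacy_grid=self.legacy_grid,
            forest=RFConfig(
                n_trees=self.n_trees,
                min_leaf_size=self.min_leaf_size,
                predictors_per_split=self.predictors_per_split,
                seed=self.seed,
            ),
            n_folds=self.folds,
            seed=self.seed,
        )

    def load_atlas(self) -> ROIAtlas:
        return read_atlas(self.atlas) if self.atlas else desikan_killiany()

    def load_cohort(self) -> CorticalAttributeCohort:
        if self.cohort_dir:
            from .io import read_cohort

            atlas = self.load_atlas()
            cdir = Path(self.cohort_dir)
            meta = cdir / "metadata.csv"
            files = sorted(cdir.glob("*_attributes.csv"))
            ids = [f.name[: -len("_attributes.csv")] for f in files]
            return read_cohort(dict(zip(ids, files)), meta, atlas)
        if self.scenario not in _SCENARIOS:
            raise ValueError(
                f"unknown scenario {self.scenario!r}; choose from "
                f"{sorted(_SCENARIOS)} or set cohort_dir"
            )
        params = _SCENARIOS[self.scenario](seed=self.seed)
        cohort, _ = synthetic.generate(params)
        return cohort


def load_run_config(path: str | Path) -> RunConfig:
    """Load a YAML/JSON run config; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    return RunConfig(**raw)


def _write_resolved(config: RunConfig, out: Path) -> None:
    (out / "resolved_config.yaml").write_text(
        yaml.safe_dump(asdict(config), sort_keys=True), encoding="utf-8"
    )


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Evaluate the pipeline per config and write the full output bundle."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    atlas = config.load_atlas()
    cohort = config.load_cohort()
    logger.info(
        "cohort: N=%d M=%d R=%d, fusion=%s",
        cohort.n_subjects, cohort.n_views, cohort.n_rois, config.fusion,
    )
    t0 = time.time()
    features = cohort_features(cohort, config.fusion, zscore_views=config.zscore_views)
    result = evaluate_cv(
        features, cohort.ages, config.pipeline_config(), subject_ids=cohort.subject_ids
    )
    logger.info(
        "evaluation done in %.1fs: r=%.3f mae=%.2f, chosen k per fold %s",
        time.time() - t0, result.pearson_r, result.mae, result.chosen_features,
    )

    paths: dict[str, Path] = {}
    paths["result"] = out / "result.json"
    paths["result"].write_text(
        json.dumps(result.summary(), indent=2, sort_keys=True), encoding="utf-8"
    )
    paths["predictions"] = out / "predictions.csv"
    result.to_frame().to_csv(paths["predictions"], index=False)

    if result.per_fold_ranks is not None:
        rel = result.relevance()
        rel_df = pd.DataFrame(
            {
                "view": [e[0] for e in rel.index_map.entries],
                "roi_i": [e[1] for e in rel.index_map.entries],
                "roi_j": [e[2] for e in rel.index_map.entries],
                "relevance_score": rel.mean_rank,
            }
        )
        paths["relevance"] = out / "relevance.csv"
        rel_df.to_csv(paths["relevance"], index=False)
        for k in config.k_list:
            edges = top_k_edges(rel, k)
            path = out / f"edges_top{k}.csv"
            write_edge_list(
                [(v, i, j, s) for v, i, j, s, _ in edges],
                atlas,
                path,
                view_names=cohort.view_names,
            )
            paths[f"edges_top{k}"] = path
    _write_resolved(config, out)
    paths["resolved_config"] = out / "resolved_config.yaml"
    return paths


def run_gap(config: RunConfig) -> dict[str, Path]:
    """Healthy-baseline gap analysis + gap-augmented classification report."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = config.load_cohort()
    features = cohort_features(cohort, config.fusion, zscore_views=config.zscore_views)
    pcfg = config.pipeline_config()
    analysis = gap_analysis(
        features, cohort.ages, cohort.groups, pcfg, subject_ids=cohort.subject_ids
    )
    paths: dict[str, Path] = {"gaps": out / "gaps.csv"}
    analysis.to_frame().to_csv(paths["gaps"], index=False)

    report: dict = {"mean_signed_gap": {
        g: analysis.mean_signed_gap(g) for g in sorted(set(cohort.groups))
    }}
    if len(set(cohort.groups)) == 2:
        report["group_difference"] = analysis.group_difference
        clf = classify_with_gap(features, cohort.ages, cohort.groups, pcfg)
        report["classification"] = clf.summary()
    paths["gap_report"] = out / "gap_report.json"
    paths["gap_report"].write_text(
        json.dumps(report, indent=2, sort_keys=True), encoding="utf-8"
    )
    _write_resolved(config, out)
    return paths


def run_bench(
    config: RunConfig, methods: list[str], fusions: list[str]
) -> pd.DataFrame:
    """Benchmark table: one row per method x fusion with R, P and MAE."""
    cohort = config.load_cohort()
    pcfg = config.pipeline_config()
    rows = []
    for fusion in fusions:
        features = cohort_features(cohort, fusion, zscore_views=config.zscore_views)
        for method in methods:
            res = run_baseline(method, features, cohort.ages, pcfg)
            rows.append(
                {"method": method, "fusion": fusion, "R": res.pearson_r,
                 "P": res.p_value, "MAE": res.mae}
            )
    return pd.DataFrame(rows)


def simulate_to_dir(
    params: synthetic.SyntheticParams, out_dir: str | Path, atlas: ROIAtlas | None = None
) -> dict[str, Path]:
    """Generate a synthetic cohort and write it in the cohort file format,
    plus a ground-truth JSON of the planted edges."""
    atlas = atlas or desikan_killiany()
    cohort, truth = synthetic.generate(params)
    paths = write_cohort(cohort, out_dir, atlas)
    gt = {
        "planted_edges": [
            {"view": v, "roi_i": i, "roi_j": j, "strength": s}
            for v, i, j, s in truth.planted_edges
        ],
        "signal_rois_per_view": {
            str(m): truth.signal_rois(m) for m in range(1, params.n_views + 1)
        },
        "acceleration_years": params.acceleration_years,
        "seed": params.seed,
    }
    gt_path = Path(out_dir) / "ground_truth.json"
    gt_path.write_text(json.dumps(gt, indent=2), encoding="utf-8")
    return {**{k: Path(v) for k, v in paths.items()}, "ground_truth": gt_path}
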