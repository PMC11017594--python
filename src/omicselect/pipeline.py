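"""End-to-end orchestration: preprocess -> screen -> discriminant -> joint -> consensus.

The stages follow the analysis order of the study the package models:
model-free MV screening ranks features per view and carries the top k
forward; the sparse discriminant is tuned by a leave-one-out lambda
path per view; the joint multi-view model is tuned by a shared-
multiplier leave-one-out search; the consensus report intersects the
three selections and augments by correlation and loading-fraction
rules.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field

import numpy as np

from . import consensus as consensus_mod
from .errors import ConfigError
from .io_tables import AlignedDataset, FeatureTable, StudyDesign, align_views, write_report
from .joint_multiview import JointFit, jaca_loocv, score_correlations
from .mvsis import ScreeningResult, mvsis_screen
from .preprocess import (
    log_cpm,
    median_normalize,
    paired_difference,
    prevalence_filter,
    relative_abundance,
    remove_feature,
)
from .sparse_discriminant import (
    DiscriminantFit,
    PathFit,
    lambda_path_loocv,
    select_model,
)
from .synthetic_data import SimulatedStudy

__all__ = ["PipelineConfig", "PipelineResult", "preprocess_view",
           "preprocess_study", "run_analysis", "run_pipeline",
           "write_artifacts", "evaluate_against_truth"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Tunable knobs of the full pipeline (defaults follow the modeled study)."""

    top_k: int = 300
    alpha: float = 0.5
    corr_threshold: float = 0.95
    top_fraction: float = 1 / 3
    mgsda_grid_size: int = 50
    jaca_grid_size: int = 20
    policy: str = "min_mcr_sparsest"
    fixed_size_k: int | None = None
    prevalence_min_samples: int = 6
    drop_features: dict = field(default_factory=dict)  # view -> [feature ids]
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.alpha < 1:
            raise ConfigError("alpha must be in [0, 1)")
        if not 0 < self.corr_threshold:
            raise ConfigError("corr_threshold must be positive")
        if not 0 <= self.top_fraction <= 1:
            raise ConfigError("top_fraction must be in [0, 1]")
        if self.top_k < 1 or self.mgsda_grid_size < 1 or self.jaca_grid_size < 1:
            raise ConfigError("grid sizes and top_k must be >= 1")


@dataclass
class PipelineResult:
    aligned: AlignedDataset
    screening: dict[str, ScreeningResult]
    mgsda_paths: dict[str, PathFit]
    mgsda_fits: dict[str, DiscriminantFit]
    joint_fit: JointFit
    reports: dict[str, "consensus_mod.ConsensusReport"]
    score_corr: dict[str, float]

    @property
    def consensus_union(self) -> set[str]:
        return set().union(*(r.selected for r in self.reports.values()))


RECIPES = ("metabolome", "microbiome", "exfoliome", "generic")


def preprocess_view(
    table: FeatureTable,
    design: StudyDesign,
    recipe: str,
    config: PipelineConfig | None = None,
) -> FeatureTable:
    """Apply one view's preprocessing, returning a subject-level table.

    Recipes: ``metabolome`` = median normalization, optional drug-feature
    removal, then day10 - day0 differences; ``microbiome`` = prevalence
    filter, relative abundance, then differences; ``exfoliome`` = day-10
    samples only, log2-CPM, rows reindexed by subject; ``generic`` =
    passthrough (table must already be subject-level).
    """
    config = config or PipelineConfig()
    if recipe not in RECIPES:
        raise ConfigError(f"unknown recipe {recipe!r}; choose from {RECIPES}")
    for fid in config.drop_features.get(recipe, []):
        table = remove_feature(table, fid)
    if recipe == "metabolome":
        return paired_difference(median_normalize(table), design)
    if recipe == "microbiome":
        filtered = prevalence_filter(table, config.prevalence_min_samples)
        return paired_difference(relative_abundance(filtered), design)
    if recipe == "exfoliome":
        day10 = design.samples_on_day(10)
        present = [s for s in table.sample_ids if s in set(day10["sample_id"])]
        sub = table.subset_samples(present)
        transformed = log_cpm(sub)
        lookup = dict(zip(day10["sample_id"], day10["subject_id"]))
        renamed = transformed.data.rename(index=lookup)
        return FeatureTable(renamed, transformed.view_kind)
    return table


def preprocess_study(
    study: SimulatedStudy | dict,
    design: StudyDesign | None = None,
    config: PipelineConfig | None = None,
    recipes: dict[str, str] | None = None,
) -> AlignedDataset:
    """Preprocess every view and align on the common subject set."""
    config = config or PipelineConfig()
    if isinstance(study, SimulatedStudy):
        views, design = study.views, study.design
    else:
        views = study
        if design is None:
            raise ConfigError("design required when passing a raw view mapping")
    recipes = recipes or {name: (name if name in RECIPES else "generic") for name in views}
    processed = {
        name: preprocess_view(tbl, design, recipes[name], config)
        for name, tbl in views.items()
    }
    return align_views(processed, design.subject_groups())


def run_analysis(aligned: AlignedDataset, config: PipelineConfig | None = None) -> PipelineResult:
    """Screen, fit both solvers, and build consensus reports per view."""
    config = config or PipelineConfig()
    y = aligned.labels
    screening: dict[str, ScreeningResult] = {}
    subset_tables: dict[str, FeatureTable] = {}
    for name, table in aligned.views.items():
        k = min(config.top_k, table.n_features)
        screen = mvsis_screen(table, y, top_k=k)
        screening[name] = screen
        keep = [f for f in table.feature_ids if f in screen.top_k_set]
        subset_tables[name] = table.subset_features(keep)

    mgsda_paths: dict[str, PathFit] = {}
    mgsda_fits: dict[str, DiscriminantFit] = {}
    for name, table in subset_tables.items():
        path = lambda_path_loocv(
            table.values, y, grid_size=config.mgsda_grid_size,
            feature_ids=table.feature_ids,
        )
        mgsda_paths[name] = path
        mgsda_fits[name] = select_model(path, config.policy, k=config.fixed_size_k)

    joint_fit = jaca_loocv(
        {name: t.values for name, t in subset_tables.items()},
        y,
        alpha=config.alpha,
        grid_size=config.jaca_grid_size,
        feature_ids={name: t.feature_ids for name, t in subset_tables.items()},
    )

    from .preprocess import standardize_fit

    std_views = {name: standardize_fit(t.values)[0] for name, t in subset_tables.items()}
    try:
        score_corr, _ = score_correlations(joint_fit, std_views)
    except Exception:  # all-zero joint fit has no scores to correlate
        score_corr = {}

    reports = {}
    for name, table in subset_tables.items():
        core = consensus_mod.intersect_selections(
            screening[name].top_k_set, mgsda_fits[name].selected,
            joint_fit.selected.get(name, set()),
        )
        reports[name] = consensus_mod.augment(
            core,
            mgsda_fits[name],
            joint_fit,
            table,
            view=name,
            corr_threshold=config.corr_threshold,
            top_fraction=config.top_fraction,
            screening_set=screening[name].top_k_set,
        )
    return PipelineResult(
        aligned=aligned,
        screening=screening,
        mgsda_paths=mgsda_paths,
        mgsda_fits=mgsda_fits,
        joint_fit=joint_fit,
        reports=reports,
        score_corr=score_corr,
    )


def evaluate_against_truth(result: PipelineResult, truth) -> dict:
    """Sensitivity/FDR of the consensus per view and on the truth union."""
    out = {}
    for name, report in result.reports.items():
        if name in truth.informative:
            sens, fdr = consensus_mod.truth_metrics(report, truth.informative[name])
            out[name] = {"sensitivity": sens, "fdr": fdr}
    union_sens, union_fdr = consensus_mod.truth_metrics(
        result.consensus_union, truth.union
    )
    out["union"] = {"sensitivity": union_sens, "fdr": union_fdr}
    return out


def run_pipeline(
    study: SimulatedStudy | dict,
    design: StudyDesign | None = None,
    config: PipelineConfig | None = None,
    out_dir: str | None = None,
) -> PipelineResult:
    """Full pipeline; optionally writes per-stage artifacts and a manifest.

    Identical config and inputs give identical outputs (every stage is
    deterministic given its inputs; randomness lives only in the data
    generator's seed).
    """
    config = config or PipelineConfig()
    aligned = preprocess_study(study, design, config)
    result = run_analysis(aligned, config)
    if out_dir is not None:
        write_artifacts(result, config, out_dir)
    return result


def write_artifacts(result: PipelineResult, config: PipelineConfig, out_dir: str) -> None:
    """Write per-stage JSON/TSV artifacts plus a manifest with config hash."""
    os.makedirs(out_dir, exist_ok=True)
    stages = []
    for name, screen in result.screening.items():
        path = os.path.join(out_dir, f"screen_{name}.json")
        with open(path, "w") as fh:
            json.dump(screen.to_dict(), fh, indent=1)
        stages.append(f"screen:{name}")
    for name, pf in result.mgsda_paths.items():
        write_report(pf, os.path.join(out_dir, f"mgsda_path_{name}.json"))
        stages.append(f"mgsda:{name}")
    write_report(result.joint_fit, os.path.join(out_dir, "jaca.json"))
    stages.append("jaca")
    for name, rep in result.reports.items():
        write_report(rep, os.path.join(out_dir, f"consensus_{name}.json"))
        stages.append(f"consensus:{name}")
    cfg = asdict(config)
    manifest = {
        "config": cfg,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest(),
        "seed": config.seed,
        "stages": ["preprocess", "align"] + stages,
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)
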