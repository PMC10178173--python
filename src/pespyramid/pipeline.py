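"""End-to-end orchestration: prepare -> pyramid -> extract -> select -> evaluate.

A single master seed fans out to per-stage seeds through a SeedSequence, so
any stage can be re-run in isolation and the whole run is a pure function of
the config.  Every intermediate artifact (manifest, features, ranking,
selection, report) is persisted alongside a config snapshot.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dataset_io, evaluation, features, relieff, synthetic

logger = logging.getLogger("pespyramid")

__all__ = ["PipelineConfig", "stage_seeds", "run_pipeline", "run_grid", "load_config"]

STAGES = ("phantom", "augment", "folds", "extract", "scale")


@dataclass
class PipelineConfig:
    """Full pipeline configuration.

    Defaults reproduce the reference configuration (512-square images,
    balanced classes, 21-image pyramid, 1000-wide logits, ReliefF with k=10,
    cubic SVM, 10-fold CV) when a real dataset and real backbone are
    supplied.  ``backbone="stub"`` selects the seeded projection stub with
    ``stub_dim`` features per image.
    """

    input_dir: str | None = None
    output_dir: str = "pespyramid_out"
    # synthetic phantoms (used when input_dir is None)
    n_per_class: int = 20
    phantom_delta: float = 10.0
    phantom_angle_sd: float = 3.0
    phantom_noise_sd: float = 8.0
    # preprocessing
    image_side: int = 512
    target_per_class: int | None = None
    pyramidal: bool = True
    # feature extraction
    backbone: str = "stub"
    stub_dim: int = 32
    # selection
    k_neighbors: int = 10
    step: int = 1
    max_prefix: int | None = None
    # classification
    svm_degree: int = 3
    box_constraint: float = 1.0
    folds: int = 10
    positive_class: str | None = None
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path, **overrides) -> PipelineConfig:
    """Load a YAML config; keyword overrides take precedence over the file."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    unknown = set(data) - {f.name for f in dataclasses.fields(PipelineConfig)}
    if unknown:
        raise dataset_io.ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    data.update({k: v for k, v in overrides.items() if v is not None})
    return PipelineConfig(**data)


def stage_seeds(master_seed: int) -> dict:
    """Fan one master seed out to named per-stage seeds (< 2**31)."""
    seq = np.random.SeedSequence(master_seed)
    children = seq.spawn(len(STAGES))
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(STAGES, children)
    }


def _make_extractor(config: PipelineConfig, seed: int) -> features.BackboneExtractor:
    if config.backbone == "stub":
        return features.make_stub_extractor(output_dim=config.stub_dim, seed=seed)
    return features.get_backbone(config.backbone)


def _prepare_manifest(config: PipelineConfig, seeds: dict) -> dataset_io.DatasetManifest:
    if config.input_dir is not None:
        manifest = dataset_io.load_dataset(config.input_dir)
    else:
        mid = 20.0
        spec = synthetic.PhantomSpec(
            n_per_class=config.n_per_class,
            side=config.image_side,
            angle_mean_flat=mid - config.phantom_delta / 2.0,
            angle_mean_normal=mid + config.phantom_delta / 2.0,
            angle_sd=config.phantom_angle_sd,
            noise_sd=config.phantom_noise_sd,
            seed=seeds["phantom"],
        )
        manifest, _ = synthetic.generate_phantoms(spec)
    if config.target_per_class is not None:
        manifest = dataset_io.balance_by_augmentation(
            manifest, config.target_per_class, rng_seed=seeds["augment"]
        )
    return manifest


def run_pipeline(config: PipelineConfig) -> tuple:
    """Execute the full pipeline; returns (EvalReport, SelectionResult).

    Stages run in order with per-stage timing logged; every artifact is
    written under ``config.output_dir``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump({"config": config.to_dict(), "stage_seeds": seeds}, fh)

    t0 = time.perf_counter()
    manifest = _prepare_manifest(config, seeds)
    logger.info("prepare: %d records %s in %.2fs", len(manifest),
                manifest.class_counts, time.perf_counter() - t0)
    dataset_io.save_manifest(manifest, out / "dataset")

    t0 = time.perf_counter()
    extractor = _make_extractor(config, seeds["extract"])
    fm = features.extract_dataset(
        extractor, manifest, side=config.image_side, pyramidal=config.pyramidal
    )
    logger.info("extract: %s matrix via %s in %.2fs", fm.values.shape,
                extractor.name, time.perf_counter() - t0)
    features.save_feature_matrix(fm, out / "features")

    t0 = time.perf_counter()
    normalized = relieff.minmax_normalize(fm)
    ranked = relieff.relieff_rank(
        normalized.values, fm.labels, relieff.ReliefFParams(k_neighbors=config.k_neighbors)
    )
    np.save(out / "relieff_weights.npy", ranked.weights)
    with open(out / "ranking.json", "w") as fh:
        json.dump(
            {"order": ranked.order.tolist(),
             "priors": {str(k): v for k, v in ranked.priors.items()}},
            fh,
        )
    logger.info("relieff: ranked %d features in %.2fs", ranked.order.size,
                time.perf_counter() - t0)

    t0 = time.perf_counter()
    svm_config = evaluation.SVMConfig(degree=config.svm_degree, C=config.box_constraint)
    evaluator = evaluation.make_svm_evaluator(
        svm_config, n_folds=config.folds, seed=seeds["folds"]
    )
    selection = relieff.iterative_select(
        fm.values, fm.labels, ranked, evaluator,
        max_prefix=config.max_prefix, step=config.step,
    )
    with open(out / "selection.json", "w") as fh:
        json.dump(
            {"prefix_sizes": selection.prefix_sizes.tolist(),
             "losses": selection.losses.tolist(),
             "best_size": selection.best_size,
             "selected_columns": selection.selected_columns.tolist()},
            fh,
        )
    logger.info("select: best prefix %d (loss %.4f) of %d evaluated in %.2fs",
                selection.best_size, selection.best_loss,
                selection.prefix_sizes.size, time.perf_counter() - t0)

    t0 = time.perf_counter()
    report = evaluation.evaluate(
        fm.values[:, selection.selected_columns], fm.labels, svm_config,
        n_folds=config.folds, seed=seeds["folds"],
        positive_class=config.positive_class,
    )
    with open(out / "report.json", "w") as fh:
        json.dump(report.to_dict(), fh)
    logger.info("evaluate: accuracy %.4f in %.2fs", report.accuracy,
                time.perf_counter() - t0)
    return report, selection


def run_grid(
    config: PipelineConfig,
    backbones: list | None = None,
    classifiers: dict | None = None,
) -> pd.DataFrame:
    """Backbone x classifier accuracy grid, in pyramidal and plain modes.

    One row per (backbone, mode), one column per classifier; written to
    ``grid.csv`` under the output directory.  Per-cell failures are logged
    and left as NaN.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    manifest = _prepare_manifest(config, seeds)
    backbones = backbones or [config.backbone]
    svm_config = evaluation.SVMConfig(degree=config.svm_degree, C=config.box_constraint)
    classifiers = classifiers or evaluation.default_classifier_registry(svm_config)

    feature_sets = {}
    for name in backbones:
        extractor = (
            features.make_stub_extractor(output_dim=config.stub_dim, seed=seeds["extract"])
            if name == "stub" else features.get_backbone(name)
        )
        for mode, pyramidal in (("pyramidal", True), ("plain", False)):
            fm = features.extract_dataset(
                extractor, manifest, side=config.image_side, pyramidal=pyramidal
            )
            feature_sets[f"{name}/{mode}"] = (fm.values, fm.labels)
    table = evaluation.grid_benchmark(
        feature_sets, classifiers, n_folds=config.folds, seed=seeds["folds"]
    )
    table.to_csv(out / "grid.csv")
    return table
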