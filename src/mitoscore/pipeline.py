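"""Workflow orchestration: simulate -> patch -> train -> score -> evaluate.

A run is described by a YAML/dict :class:`RunConfig` (validated strictly —
unknown keys are rejected), executed into a run directory with one
sub-directory per stage.  Each stage records a hash of the configuration
slice and seed it depends on; re-running with an identical configuration
reuses the cached stage outputs.  A single root seed is fanned out
deterministically to every stage, so one integer reproduces a whole run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict

from mitoscore import cnn, evalstats, imaging_io, mc_scoring, morphometry, segpatch, simcell
from mitoscore.simcell import _child_seed

logger = logging.getLogger(__name__)


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateConfig(_Strict):
    n_fields_per_class: int = 30
    field_size_px: int = 512
    noise_level: float = 0.05
    n_experiments: int = 5
    phi_jitter: float = 0.08


class PatchConfig(_Strict):
    patch_size: int = 112
    stride: int = 100
    min_fg: float = 0.5
    seg_sigma: float = 8.0
    min_object_px: int = 2000


class TrainStageConfig(_Strict):
    tasks: list[str] = ["CCCP-FL3-NC"]
    epochs: int = 10
    lr: float = 2e-3
    batch_size: int = 32
    out_size: int = 64
    channels: tuple[int, int] = (8, 16)
    max_patches_per_field: int = 32
    train_stride: int = 56  # denser tiling than scoring: more patches/field


class ScoreConfig(_Strict):
    rounds: int = 100
    k: int = 4


class EvaluateConfig(_Strict):
    n_folds: int = 5
    test_fold: int = 0


#: full-resolution profile: the acquisition-scale recipe (224-px inputs,
#: 200 epochs, batch 128, lr 1e-4, 100-round scoring)
PAPER_PROFILE_OVERRIDES = {
    "train": {"epochs": 200, "lr": 1e-4, "batch_size": 128, "out_size": 224, "train_stride": 100},
    "score": {"rounds": 100, "k": 4},
    "simulate": {"field_size_px": 2048},
}


class RunConfig(_Strict):
    profile: Literal["desk", "paper"] = "desk"
    seed: int = 0
    simulate: SimulateConfig = SimulateConfig()
    patch: PatchConfig = PatchConfig()
    train: TrainStageConfig = TrainStageConfig()
    score: ScoreConfig = ScoreConfig()
    evaluate: EvaluateConfig = EvaluateConfig()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        if raw.get("profile") == "paper":
            merged = {k: dict(v) for k, v in PAPER_PROFILE_OVERRIDES.items()}
            for section, values in raw.items():
                if isinstance(values, dict):
                    merged.setdefault(section, {}).update(values)
                else:
                    merged[section] = values
            raw = merged
        return cls.model_validate(raw)


def _hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _stage_cached(stage_dir: Path, stage_hash: str) -> bool:
    marker = stage_dir / "stage_hash.json"
    if marker.exists() and json.loads(marker.read_text()).get("hash") == stage_hash:
        return True
    return False


def _mark_stage(stage_dir: Path, stage_hash: str) -> None:
    stage_dir.mkdir(parents=True, exist_ok=True)
    (stage_dir / "stage_hash.json").write_text(json.dumps({"hash": stage_hash}))


def run_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """Execute all stages into ``out_dir``; cached stages are reused.

    Returns the run directory.  Stage layout: ``dataset/`` (fields, masks,
    manifest), ``patch/`` (classical foreground masks + patch index),
    ``models/<task>/``, ``scores_<task>.csv`` and ``report/``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = config.seed

    # --- simulate -----------------------------------------------------------
    sim_dir = out_dir / "dataset"
    sim_hash = _hash({"simulate": config.simulate.model_dump(), "seed": seed})
    if not _stage_cached(sim_dir, sim_hash):
        logger.info("stage simulate: generating %d fields/class", config.simulate.n_fields_per_class)
        specs = simcell.default_class_specs(config.simulate.field_size_px, config.simulate.noise_level)
        simcell.generate_dataset(
            specs,
            config.simulate.n_fields_per_class,
            sim_dir,
            seed=_child_seed(seed, 1),
            n_experiments=config.simulate.n_experiments,
            phi_jitter=config.simulate.phi_jitter,
        )
        _mark_stage(sim_dir, sim_hash)
    else:
        logger.info("stage simulate: cache hit")
    manifest = imaging_io.load_manifest(sim_dir / "manifest.csv")

    # --- patch (classical foreground masks + patch index) -------------------
    patch_dir = out_dir / "patch"
    patch_hash = _hash({"patch": config.patch.model_dump(), "sim": sim_hash})
    if not _stage_cached(patch_dir, patch_hash):
        logger.info("stage patch: segmenting foreground and indexing patches")
        (patch_dir / "masks").mkdir(parents=True, exist_ok=True)
        index_rows = []
        for rec in manifest.to_dict("records"):
            image = imaging_io.normalize_percentile(imaging_io.max_project(imaging_io.read_field(rec["path"])))
            fg = segpatch.segment_foreground(
                image, sigma=config.patch.seg_sigma, min_object_px=config.patch.min_object_px
            )
            imaging_io.write_field(fg.mask.astype(np.uint8) * 255, patch_dir / "masks" / f"{rec['field_id']}.tif")
            for p in segpatch.tile_patches(image, fg, config.patch.patch_size, config.patch.stride):
                index_rows.append(
                    {
                        "field_id": rec["field_id"],
                        "origin_r": p.origin_rc[0],
                        "origin_c": p.origin_rc[1],
                        "fg_fraction": p.fg_fraction,
                    }
                )
        pd.DataFrame(index_rows).to_csv(patch_dir / "patch_index.csv", index=False)
        _mark_stage(patch_dir, patch_hash)
    else:
        logger.info("stage patch: cache hit")

    # the remaining stages read fields with the classical masks
    manifest = manifest.copy()
    manifest["mask_path"] = [str(patch_dir / "masks" / f"{fid}.tif") for fid in manifest["field_id"]]

    folds = evalstats.make_grouped_folds(manifest, n_folds=config.evaluate.n_folds, seed=_child_seed(seed, 2))
    test_exps = set(folds.test_experiments(config.evaluate.test_fold))
    train_manifest = manifest[~manifest["experiment_id"].isin(test_exps)]
    test_manifest = manifest[manifest["experiment_id"].isin(test_exps)]

    # --- train ---------------------------------------------------------------
    models: dict[str, cnn.TrainedModel] = {}
    for task in config.train.tasks:
        model_dir = out_dir / "models" / task
        train_hash = _hash({"train": config.train.model_dump(), "task": task, "patch": patch_hash, "fold": config.evaluate.test_fold, "seed": seed})
        if not _stage_cached(model_dir, train_hash):
            logger.info("stage train: task %s on %d fields", task, len(train_manifest))
            patches = _collect_training_patches(train_manifest, task, config, seed)
            tc = cnn.TrainConfig(
                task=task,
                epochs=config.train.epochs,
                lr=config.train.lr,
                batch_size=config.train.batch_size,
                channels=tuple(config.train.channels),
                seed=_child_seed(seed, 3),
                augment=cnn.AugmentSpec(out_size=config.train.out_size),
            )
            model = cnn.train(patches, tc)
            model.save(model_dir)
            _mark_stage(model_dir, train_hash)
        else:
            logger.info("stage train: cache hit for %s", task)
            model = cnn.TrainedModel.load(model_dir)
        models[task] = model

    # --- score ---------------------------------------------------------------
    score_tables: dict[str, pd.DataFrame] = {}
    for task, model in models.items():
        score_path = out_dir / f"scores_{task}.csv"
        classes = cnn.TASKS[task]
        sub = test_manifest[test_manifest["label"].isin(classes)]
        table = mc_scoring.score_cohort(
            model, sub, rounds=config.score.rounds, k=config.score.k,
            seed=_child_seed(seed, 4),
            patch_size=config.patch.patch_size, stride=config.patch.stride, min_fg=config.patch.min_fg,
        )
        table.to_csv(score_path, index=False)
        score_tables[task] = table

    # --- evaluate -------------------------------------------------------------
    report_dir = out_dir / "report"
    report_dir.mkdir(exist_ok=True)
    summary: dict[str, object] = {"n_test_fields": int(len(test_manifest))}
    for task, table in score_tables.items():
        classes = cnn.TASKS[task]
        score_cols = [f"score_{c}" for c in classes]
        pred = [classes[i] for i in table[score_cols].to_numpy().argmax(axis=1)]
        if len(classes) == 2:
            m = evalstats.classification_metrics(table["label"], pred, positive_label=classes[0])
            if table["label"].nunique() == 2:
                m["roc_auc"] = evalstats.roc_auc(
                    table[f"score_{classes[0]}"], table["label"], positive_label=classes[0]
                ).auc
        else:
            m = evalstats.classification_metrics(table["label"], pred, average="macro")
        summary[task] = m
    folds.counts_table(manifest).to_csv(report_dir / "fold_counts.csv", index=False)
    (report_dir / "summary.json").write_text(json.dumps(summary, indent=2))

    run_manifest = {
        "config": config.model_dump(),
        "seed": seed,
        "config_hash": _hash(config.model_dump()),
        "stages": {"simulate": sim_hash, "patch": patch_hash},
        "artifacts": sorted(str(p.relative_to(out_dir)) for p in out_dir.rglob("*") if p.is_file()),
    }
    (out_dir / "run.json").write_text(json.dumps(run_manifest, indent=2, default=str))
    return out_dir


def _collect_training_patches(train_manifest: pd.DataFrame, task: str, config: RunConfig, seed: int):
    classes = cnn.TASKS[task]
    patches = []
    for i, rec in enumerate(train_manifest.to_dict("records")):
        if rec["label"] not in classes:
            continue
        image = imaging_io.normalize_percentile(imaging_io.max_project(imaging_io.read_field(rec["path"])))
        mask = imaging_io.read_field(rec["mask_path"]) > 0
        pool = segpatch.patch_pool(image, mask, config.patch.patch_size, config.train.train_stride, config.patch.min_fg)
        if not pool:
            logger.warning("field %s yields no training patches", rec["field_id"])
            continue
        rng = np.random.default_rng(_child_seed(seed, 0xA11, i))
        take = min(config.train.max_patches_per_field, len(pool))
        for j in rng.choice(len(pool), size=take, replace=False):
            patches.append((pool[j].pixels, rec["label"]))
    return patches


def field_morphometry_table(manifest: pd.DataFrame, seg_sigma: float = 8.0) -> pd.DataFrame:
    """Classical morphometry summary for every field of a manifest."""
    rows = []
    for rec in manifest.to_dict("records"):
        image = imaging_io.normalize_percentile(imaging_io.max_project(imaging_io.read_field(rec["path"])))
        if rec.get("mask_path"):
            mask = imaging_io.read_field(rec["mask_path"]) > 0
        else:
            mask = segpatch.segment_foreground(image, sigma=seg_sigma).mask
        summary = morphometry.field_morphometry(image, mask)
        rows.append({"field_id": rec["field_id"], "label": rec.get("label", ""), **summary.to_dict()})
    return pd.DataFrame(rows)
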