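"""End-to-end virtual clinical trial orchestration.

Pipeline: population sampling -> phantom voxelization -> acquisition under
the three geometries -> simple backprojection -> training of the four
segmentation models -> slice-wise distance-binned evaluation and tables.

The four models map to fixed (geometry, loss) pairs:

====== ============ =======================================
model  geometry     loss
====== ============ =======================================
I_1    conventional tissue FTL only (loss 1)
I_1&2  conventional combined tissue + outline FTL (loss 1&2)
II_1&2 T            combined
III_1&2 XWR         combined
====== ============ =======================================

``run_vct`` materializes every stage on disk and is resumable per stage;
``directional_study`` runs the same pipeline in memory at a chosen scale
and returns the headline per-model metrics.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluation
from .dataset import Sample
from .geometry import DetectorSpec, make_geometry
from .loss import LossConfig
from .phantom import (LabelVolume, PopulationSpec, build_phantom,
                      population_manifest, sample_population)
from .projector import MaterialTable, forward_project
from .reconstructor import backproject
from .segmenter import TrainConfig, UNetConfig, argmax_labels, predict, train

MODEL_IDS = ("I_1", "I_1&2", "II_1&2", "III_1&2")
MODEL_GEOMETRY = {"I_1": "conventional", "I_1&2": "conventional",
                  "II_1&2": "t", "III_1&2": "xwr"}
GEOMETRY_KINDS = ("conventional", "t", "xwr")


def model_loss_config(model_id: str) -> LossConfig:
    """Loss configuration of a study model: I_1 uses loss (1) alone."""
    if model_id not in MODEL_IDS:
        raise ValueError(f"unknown model id {model_id!r}")
    return LossConfig(lambda_outline=0.0 if model_id == "I_1" else 1.0)


@dataclass(frozen=True)
class ExperimentConfig:
    """Desk-scale study configuration (full-scale values are config-legal
    but sized for cluster hardware)."""

    n_train_phantoms: int = 5
    n_eval_phantoms: int = 6
    voxel_mm: float = 3.0
    detector_pitch_mm: float = 4.0
    detector_n_u: int = 52
    detector_n_v: int = 66
    detector_gap_mm: float = 25.0
    sid_mm: float = 620.0
    min_block_mm: float = 6.0
    max_epochs: int = 12
    batch_size: int = 2
    learning_rate: float = 0.01
    checkpoint_every: int = 5
    unet_depth: int = 2
    unet_base_channels: int = 8
    master_seed: int = 0
    out_dir: str = "runs/study"

    def detector(self) -> DetectorSpec:
        return DetectorSpec(pixel_pitch_mm=self.detector_pitch_mm,
                            n_u=self.detector_n_u, n_v=self.detector_n_v,
                            gap_mm=self.detector_gap_mm)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)


def _stage_seeds(master_seed: int) -> dict[str, int]:
    """Fan the master seed out to per-stage seeds (stable, < 2**31)."""
    out = {}
    for name in ("population", "train", "noise"):
        digest = hashlib.sha256(f"{master_seed}:{name}".encode()).digest()
        out[name] = int.from_bytes(digest[:4], "little") % (2**31 - 1)
    return out


def build_population(cfg: ExperimentConfig):
    """Sample the population and voxelize all phantoms."""
    seeds = _stage_seeds(cfg.master_seed)
    spec = PopulationSpec(
        n_phantoms=cfg.n_train_phantoms + cfg.n_eval_phantoms,
        voxel_mm=cfg.voxel_mm, seed=seeds["population"],
    )
    params = sample_population(spec)
    volumes = [build_phantom(p, cfg.voxel_mm, min_block_mm=cfg.min_block_mm)
               for p in params]
    return params, volumes


def acquire(volumes: list[LabelVolume], geometry_kind: str,
            cfg: ExperimentConfig,
            materials: MaterialTable | None = None) -> list[Sample]:
    """Project and reconstruct every phantom under one geometry."""
    materials = materials or MaterialTable()
    det = cfg.detector()
    kwargs = {} if geometry_kind == "xwr" else {"sid_mm": cfg.sid_mm}
    geom = make_geometry(geometry_kind, detector=det, **kwargs)
    samples = []
    for i, vol in enumerate(volumes):
        proj = forward_project(vol, geom, materials)
        recon = backproject(proj, geom, grid_shape=vol.shape,
                            voxel_mm=vol.voxel_mm)
        samples.append(Sample(recon=recon, mask=vol, phantom_id=i,
                              geometry_name=geom.name))
    return samples


def _evaluate_model(model, eval_samples: list[Sample],
                    model_id: str) -> list[evaluation.SliceRecord]:
    records = []
    for s in eval_samples:
        prob = predict(model, s.recon)
        pred = argmax_labels(prob, voxel_mm=s.recon.voxel_mm)
        for z in range(s.mask.shape[2]):
            records.append(evaluation.confusion_per_slice(
                pred, s.mask, z, phantom_id=s.phantom_id, model_id=model_id))
    return records


def directional_study(master_seed: int,
                      cfg: ExperimentConfig | None = None) -> dict:
    """Run the four-model study in memory and return headline metrics.

    Returns a dict with, per model: mean air Jaccard distance over
    evaluation slices, mean adipose and dense Jaccard indices, the
    distance-binned table, and the pairwise improvement percentages in air
    classification that summarize the study.
    """
    cfg = cfg or ExperimentConfig(master_seed=master_seed)
    if cfg.master_seed != master_seed:
        cfg = ExperimentConfig(**{**asdict(cfg), "master_seed": master_seed})
    seeds = _stage_seeds(master_seed)

    params, volumes = build_population(cfg)
    train_vols = volumes[:cfg.n_train_phantoms]
    eval_vols = volumes[cfg.n_train_phantoms:]

    samples_by_geom = {}
    for kind in GEOMETRY_KINDS:
        samples_by_geom[kind] = {
            "train": acquire(train_vols, kind, cfg),
            "eval": acquire(eval_vols, kind, cfg),
        }

    unet_cfg = UNetConfig(depth=cfg.unet_depth,
                          base_channels=cfg.unet_base_channels)
    train_cfg = TrainConfig(learning_rate=cfg.learning_rate,
                            batch_size=cfg.batch_size,
                            checkpoint_every=cfg.checkpoint_every,
                            max_epochs=cfg.max_epochs, seed=seeds["train"])

    results: dict = {"models": {}, "config": asdict(cfg)}
    all_records: dict[str, list] = {}
    for model_id in MODEL_IDS:
        kind = MODEL_GEOMETRY[model_id]
        model, history = train(samples_by_geom[kind]["train"],
                               loss_cfg=model_loss_config(model_id),
                               unet_cfg=unet_cfg, train_cfg=train_cfg)
        records = _evaluate_model(model, samples_by_geom[kind]["eval"],
                                  model_id)
        all_records[model_id] = records
        frame = evaluation.records_frame(records)
        summary = {}
        for cls in ("air", "adipose", "dense"):
            sub = frame[frame["class"] == cls]
            summary[f"{cls}_jaccard"] = float(np.nanmean(sub["jaccard"]))
            summary[f"{cls}_jaccard_distance"] = float(
                np.nanmean(sub["jaccard_distance"]))
            summary[f"{cls}_dice"] = float(np.nanmean(sub["dice"]))
            summary[f"{cls}_precision"] = float(np.nanmean(sub["precision"]))
            summary[f"{cls}_recall"] = float(np.nanmean(sub["recall"]))
            summary[f"{cls}_accuracy"] = float(np.nanmean(sub["accuracy"]))
        results["models"][model_id] = {
            "summary": summary,
            "history": history,
            "bins": evaluation.bin_by_distance(records),
        }

    jd = {m: results["models"][m]["summary"]["air_jaccard_distance"]
          for m in MODEL_IDS}
    results["air_jd"] = jd
    results["improvements_pct"] = {
        "I_1&2/I_1": evaluation.improvement(jd["I_1"], jd["I_1&2"]),
        "II_1&2/I_1&2": evaluation.improvement(jd["I_1&2"], jd["II_1&2"]),
        "II_1&2/III_1&2": evaluation.improvement(jd["III_1&2"], jd["II_1&2"]),
        "III_1&2/I_1": evaluation.improvement(jd["I_1"], jd["III_1&2"]),
    }
    results["records"] = all_records
    return results


def make_tables(results: dict, out_dir=None) -> dict[str, pd.DataFrame]:
    """Emit the study's summary tables (air-outline, tissue Jaccard,
    overall metrics) from a directional-study result."""
    bins = {m: results["models"][m]["bins"] for m in MODEL_IDS}

    def _pivot(cls: str, metric: str) -> pd.DataFrame:
        frames = []
        for m, b in bins.items():
            sub = b[b["class"] == cls][["bin", "d_mean_mm",
                                        f"{metric}_mean", f"{metric}_sd",
                                        "n_slices"]].copy()
            sub["model_id"] = m
            frames.append(sub)
        long = pd.concat(frames, ignore_index=True)
        wide = long.pivot_table(index=["bin", "d_mean_mm"],
                                columns="model_id",
                                values=f"{metric}_mean").reset_index()
        return wide

    table3 = _pivot("air", "jaccard_distance")
    for ref, new in (("I_1", "I_1&2"), ("I_1", "II_1&2"), ("I_1", "III_1&2"),
                     ("I_1&2", "II_1&2"), ("III_1&2", "II_1&2")):
        col = f"improvement_{new}/{ref}_pct"
        table3[col] = 100.0 * (table3[ref] - table3[new]) / table3[ref]

    table4 = pd.merge(
        _pivot("adipose", "jaccard"), _pivot("dense", "jaccard"),
        on=["bin", "d_mean_mm"], suffixes=("_adipose", "_dense"))

    rows = []
    for m in MODEL_IDS:
        s = results["models"][m]["summary"]
        for cls in ("adipose", "dense"):
            rows.append({
                "model_id": m, "tissue": cls,
                "dice": s[f"{cls}_dice"], "precision": s[f"{cls}_precision"],
                "recall": s[f"{cls}_recall"],
                "accuracy": s[f"{cls}_accuracy"],
            })
    table5 = pd.DataFrame(rows)

    tables = {"table3": table3, "table4": table4, "table5": table5}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, t in tables.items():
            t.to_csv(out_dir / f"{name}.csv", index=False)
    return tables


# ---------------------------------------------------------------------------
# on-disk, stage-resumable runner
# ---------------------------------------------------------------------------

def _config_hash(payload) -> str:
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()


def _stage_done(stage_dir: Path, digest: str) -> bool:
    marker = stage_dir / ".stage.json"
    if not marker.exists():
        return False
    try:
        return json.loads(marker.read_text()).get("hash") == digest
    except (json.JSONDecodeError, OSError):
        return False


def _mark_stage(stage_dir: Path, digest: str) -> None:
    (stage_dir / ".stage.json").write_text(
        json.dumps({"hash": digest, "time": time.time()}))


def _model_slug(model_id: str) -> str:
    return model_id.replace("&", "and").replace("/", "_")


def run_vct(cfg: ExperimentConfig) -> dict:
    """Full on-disk pipeline run.

    Stages (phantoms, recons per geometry, one trained model per study
    model, evaluation) each live in their own directory under
    ``cfg.out_dir`` with a content-hash marker; a stage whose marker
    matches the configuration is skipped on resume, so deleting one
    stage's outputs re-runs only that stage and its dependents.
    """
    from .reconstructor import ReconVolume
    from .segmenter import UNet3D

    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(cfg.master_seed)
    n_total = cfg.n_train_phantoms + cfg.n_eval_phantoms

    # -- stage 1: phantoms --------------------------------------------------
    phantom_keys = {k: getattr(cfg, k) for k in
                    ("n_train_phantoms", "n_eval_phantoms", "voxel_mm",
                     "min_block_mm", "master_seed")}
    phantom_digest = _config_hash(phantom_keys)
    phantom_dir = out / "phantoms"
    phantom_dir.mkdir(exist_ok=True)
    if not _stage_done(phantom_dir, phantom_digest):
        params, volumes = build_population(cfg)
        for i, v in enumerate(volumes):
            v.save(phantom_dir / f"phantom{i:03d}.nii.gz")
        population_manifest(params, volumes).to_csv(
            phantom_dir / "population.csv", index=False)
        _mark_stage(phantom_dir, phantom_digest)
    else:
        volumes = [LabelVolume.load(phantom_dir / f"phantom{i:03d}.nii.gz")
                   for i in range(n_total)]

    # -- stage 2: acquisition + reconstruction per geometry -----------------
    acq_keys = {**phantom_keys, "detector_pitch_mm": cfg.detector_pitch_mm,
                "detector_n_u": cfg.detector_n_u,
                "detector_n_v": cfg.detector_n_v,
                "detector_gap_mm": cfg.detector_gap_mm, "sid_mm": cfg.sid_mm}
    samples_by_geom: dict[str, list[Sample]] = {}
    for kind in GEOMETRY_KINDS:
        digest = _config_hash({**acq_keys, "geometry": kind})
        gdir = out / "recons" / kind
        gdir.mkdir(parents=True, exist_ok=True)
        if not _stage_done(gdir, digest):
            samples = acquire(volumes, kind, cfg)
            for s in samples:
                s.recon.save(gdir / f"phantom{s.phantom_id:03d}_recon.nii.gz")
            _mark_stage(gdir, digest)
        else:
            samples = []
            for i, vol in enumerate(volumes):
                recon = ReconVolume.load(gdir / f"phantom{i:03d}_recon.nii.gz")
                samples.append(Sample(recon=recon, mask=vol, phantom_id=i,
                                      geometry_name=kind))
        samples_by_geom[kind] = samples

    # -- stage 3: training, one model per study arm -------------------------
    unet_cfg = UNetConfig(depth=cfg.unet_depth,
                          base_channels=cfg.unet_base_channels)
    train_cfg = TrainConfig(learning_rate=cfg.learning_rate,
                            batch_size=cfg.batch_size,
                            checkpoint_every=cfg.checkpoint_every,
                            max_epochs=cfg.max_epochs, seed=seeds["train"])
    train_keys = {**acq_keys, "max_epochs": cfg.max_epochs,
                  "batch_size": cfg.batch_size,
                  "learning_rate": cfg.learning_rate,
                  "unet_depth": cfg.unet_depth,
                  "unet_base_channels": cfg.unet_base_channels}
    models = {}
    for model_id in MODEL_IDS:
        digest = _config_hash({**train_keys, "model": model_id})
        mdir = out / "models" / _model_slug(model_id)
        mdir.mkdir(parents=True, exist_ok=True)
        weights = mdir / "weights.npz"
        if not _stage_done(mdir, digest):
            kind = MODEL_GEOMETRY[model_id]
            train_samples = samples_by_geom[kind][:cfg.n_train_phantoms]
            model, history = train(train_samples,
                                   loss_cfg=model_loss_config(model_id),
                                   unet_cfg=unet_cfg, train_cfg=train_cfg)
            model.save(weights)
            pd.DataFrame(history).to_csv(mdir / "history.csv", index=False)
            _mark_stage(mdir, digest)
        else:
            model = UNet3D.load(weights)
        models[model_id] = model

    # -- stage 4: evaluation + tables ---------------------------------------
    results: dict = {"models": {}, "config": asdict(cfg), "seeds": seeds}
    for model_id in MODEL_IDS:
        kind = MODEL_GEOMETRY[model_id]
        eval_samples = samples_by_geom[kind][cfg.n_train_phantoms:]
        records = _evaluate_model(models[model_id], eval_samples, model_id)
        frame = evaluation.records_frame(records)
        summary = {}
        for cls in ("air", "adipose", "dense"):
            sub = frame[frame["class"] == cls]
            for metric in evaluation.METRIC_NAMES:
                summary[f"{cls}_{metric}"] = float(np.nanmean(sub[metric]))
        results["models"][model_id] = {
            "summary": summary,
            "history": pd.read_csv(out / "models" / _model_slug(model_id)
                                   / "history.csv").to_dict("records"),
            "bins": evaluation.bin_by_distance(records),
        }

    jd = {m: results["models"][m]["summary"]["air_jaccard_distance"]
          for m in MODEL_IDS}
    results["air_jd"] = jd
    results["improvements_pct"] = {
        "I_1&2/I_1": evaluation.improvement(jd["I_1"], jd["I_1&2"]),
        "II_1&2/I_1&2": evaluation.improvement(jd["I_1&2"], jd["II_1&2"]),
        "II_1&2/III_1&2": evaluation.improvement(jd["III_1&2"], jd["II_1&2"]),
        "III_1&2/I_1": evaluation.improvement(jd["I_1"], jd["III_1&2"]),
    }
    eval_dir = out / "eval"
    eval_dir.mkdir(exist_ok=True)
    make_tables(results, out_dir=eval_dir)
    with open(out / "manifest.json", "w") as fh:
        json.dump({"config": asdict(cfg), "seeds": seeds,
                   "air_jd": results["air_jd"],
                   "improvements_pct": results["improvements_pct"]},
                  fh, indent=2)
    return results
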