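"""Slice-wise, distance-binned segmentation metrics and model comparisons.

Segmentation quality in tomosynthesis depends strongly on the slice
position: slices near the paddle and support (large |d|, where d is the
signed distance to the central slice, negative toward the support) sit in
the convex-hull region of the breast outline and suffer the worst
air/tissue misclassification.  This module computes per-slice confusion
counts, the standard overlap metrics, pools slices from phantoms of
different thickness into 10 equal-count distance bins, and compares models
with non-parametric rank tests (Kruskal-Wallis omnibus, Wilcoxon-Mann-
Whitney pairwise).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .phantom import AIR, ADIPOSE, DENSE, LabelVolume

METRIC_NAMES = ("jaccard", "dice", "precision", "recall", "accuracy",
                "jaccard_distance")
CLASS_NAMES = {AIR: "air", ADIPOSE: "adipose", DENSE: "dense"}


@dataclass
class SliceRecord:
    """Per-slice one-vs-rest confusion counts for each class."""

    phantom_id: int
    model_id: str
    z: int
    d_mm: float
    counts: dict[int, tuple[int, int, int, int]]  # class -> (TP, FP, FN, TN)


def slice_distance(z: int, n_slices: int, voxel_mm: float) -> float:
    """Signed distance (mm) of slice ``z`` to the central slice.

    Negative toward the breast support (z = 0 side).
    """
    if n_slices < 1:
        raise ValueError("volume must have at least one slice")
    z_central = (n_slices - 1) // 2
    return (z - z_central) * voxel_mm


def confusion_per_slice(pred: LabelVolume, truth: LabelVolume, z: int,
                        phantom_id: int = 0, model_id: str = "") -> SliceRecord:
    """One-vs-rest TP/FP/FN/TN per class on slice ``z``."""
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must be congruent")
    p = pred.labels[:, :, z]
    t = truth.labels[:, :, z]
    n = p.size
    counts = {}
    for c in (AIR, ADIPOSE, DENSE):
        pc = p == c
        tc = t == c
        tp = int((pc & tc).sum())
        fp = int((pc & ~tc).sum())
        fn = int((~pc & tc).sum())
        counts[c] = (tp, fp, fn, n - tp - fp - fn)
    d = slice_distance(z, pred.shape[2], pred.voxel_mm)
    return SliceRecord(phantom_id=phantom_id, model_id=model_id, z=z,
                       d_mm=d, counts=counts)


def metrics(rec: SliceRecord, c: int) -> dict[str, float]:
    """Overlap metrics of class ``c`` for one slice.

    Ratio metrics are NaN when undefined (empty union / empty prediction /
    empty truth); such slices are excluded from bin means downstream.
    """
    tp, fp, fn, tn = rec.counts[c]
    union = tp + fp + fn
    total = tp + fp + fn + tn
    j = tp / union if union else np.nan
    return {
        "jaccard": j,
        "dice": 2 * tp / (2 * tp + fp + fn) if union else np.nan,
        "precision": tp / (tp + fp) if tp + fp else np.nan,
        "recall": tp / (tp + fn) if tp + fn else np.nan,
        "accuracy": (tp + tn) / total,
        "jaccard_distance": 1.0 - j if union else np.nan,
    }


def records_frame(records: list[SliceRecord]) -> pd.DataFrame:
    """Long-form metric table: one row per (slice, class)."""
    rows = []
    for rec in records:
        for c, name in CLASS_NAMES.items():
            row = {
                "phantom_id": rec.phantom_id,
                "model_id": rec.model_id,
                "z": rec.z,
                "d_mm": rec.d_mm,
                "class": name,
            }
            row.update(metrics(rec, c))
            rows.append(row)
    return pd.DataFrame(rows)


def bin_by_distance(records: list[SliceRecord], n_bins: int = 10) -> pd.DataFrame:
    """Pool slices into ``n_bins`` equal-count bins of d and summarize.

    The pooled d values (one per slice, across phantoms and models of the
    same slice set) are split into equal-count bins (counts equal +/-1);
    each bin is labelled by its mean d.  Returns a long-form table with
    per-bin, per-model, per-class mean and SD of each metric plus counts of
    slices excluded because a ratio metric was undefined.
    """
    frame = records_frame(records)
    slices = frame[["phantom_id", "model_id", "z", "d_mm"]].drop_duplicates()
    if len(slices) < n_bins:
        raise ValueError(f"need at least {n_bins} slices")
    d_sorted_idx = np.argsort(slices["d_mm"].to_numpy(), kind="stable")
    assignments = np.empty(len(slices), dtype=np.int64)
    for b, chunk in enumerate(np.array_split(d_sorted_idx, n_bins)):
        assignments[chunk] = b
    slices = slices.assign(bin=assignments)
    frame = frame.merge(slices, on=["phantom_id", "model_id", "z", "d_mm"])

    out = []
    for (b, model, cls), grp in frame.groupby(["bin", "model_id", "class"]):
        row = {"bin": b, "model_id": model, "class": cls,
               "d_mean_mm": grp["d_mm"].mean(), "n_slices": len(grp)}
        for m in METRIC_NAMES:
            vals = grp[m].to_numpy(dtype=float)
            good = vals[~np.isnan(vals)]
            row[f"{m}_mean"] = good.mean() if good.size else np.nan
            row[f"{m}_sd"] = good.std(ddof=1) if good.size > 1 else np.nan
            row[f"{m}_excluded"] = int(np.isnan(vals).sum())
        out.append(row)
    return pd.DataFrame(out).sort_values(["class", "model_id", "bin"],
                                         ignore_index=True)


def improvement(jd_ref: float, jd_new: float) -> float:
    """Percent reduction of a Jaccard distance relative to a reference."""
    if jd_ref <= 0:
        raise ValueError("reference Jaccard distance must be positive")
    return 100.0 * (jd_ref - jd_new) / jd_ref


def compare_models(samples_by_model: dict[str, np.ndarray],
                   holm: bool = False) -> dict:
    """Kruskal-Wallis omnibus + pairwise Wilcoxon-Mann-Whitney tests.

    ``samples_by_model`` maps a model id to its per-slice metric samples.
    Raw p-values are reported; Holm correction of the pairwise family is
    optional and off by default.
    """
    models = list(samples_by_model)
    if len(models) < 2:
        raise ValueError("need at least two models")
    groups = [np.asarray(samples_by_model[m], dtype=float) for m in models]
    for m, grp in zip(models, groups):
        if grp.size < 2:
            raise ValueError(f"model {m!r} has fewer than 2 samples")
    h, p_omnibus = stats.kruskal(*groups)
    pairs = {}
    for i in range(len(models)):
        for j in range(i + 1, len(models)):
            method = "exact" if (len(groups[i]) <= 20 and len(groups[j]) <= 20
                                 and not _has_ties(groups[i], groups[j])) else "asymptotic"
            res = stats.mannwhitneyu(groups[i], groups[j],
                                     alternative="two-sided", method=method)
            pairs[(models[i], models[j])] = float(res.pvalue)
    if holm:
        keys = sorted(pairs, key=pairs.get)
        m = len(keys)
        adj, running = {}, 0.0
        for rank, k in enumerate(keys):
            running = max(running, min(1.0, (m - rank) * pairs[k]))
            adj[k] = running
        pairs = adj
    return {"kruskal_h": float(h), "kruskal_p": float(p_omnibus),
            "pairwise_p": pairs}


def _has_ties(a: np.ndarray, b: np.ndarray) -> bool:
    merged = np.concatenate([a, b])
    return len(np.unique(merged)) != merged.size


# colour palette (RGB): correct air / adipose / dense, then error classes
_PALETTE = {
    "blue": (0, 0, 255),      # TN background (correct air)
    "gray": (128, 128, 128),  # correct adipose
    "white": (255, 255, 255), # correct dense
    "red": (255, 0, 0),       # FP or FN background (air errors)
    "yellow": (255, 255, 0),  # FP or FN dense tissue
}


def accuracy_colormap(pred: LabelVolume, truth: LabelVolume,
                      z: int) -> tuple[np.ndarray, dict[str, int]]:
    """Categorical accuracy image of slice ``z`` plus category counts.

    Correct voxels use the mask palette (blue air, gray adipose, white
    dense); any error touching air is red; the remaining errors
    (adipose <-> dense confusions, i.e. dense FP or FN) are yellow.
    """
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must be congruent")
    p = pred.labels[:, :, z]
    t = truth.labels[:, :, z]
    img = np.zeros(p.shape + (3,), dtype=np.uint8)
    cats = {
        "blue": (p == AIR) & (t == AIR),
        "gray": (p == ADIPOSE) & (t == ADIPOSE),
        "white": (p == DENSE) & (t == DENSE),
        "red": (p != t) & ((p == AIR) | (t == AIR)),
        "yellow": (p != t) & (p != AIR) & (t != AIR),
    }
    counts = {}
    for name, m in cats.items():
        img[m] = _PALETTE[name]
        counts[name] = int(m.sum())
    return img, counts


def save_colormap(img: np.ndarray, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    plt.imsave(str(path), np.transpose(img, (1, 0, 2)), origin="lower")
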