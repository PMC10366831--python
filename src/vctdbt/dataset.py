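"""Harmonize ground-truth masks and reconstructions into samples.

The full-scale study pairs 0.100 mm phantom masks with 0.085 mm
reconstructions and downsamples both to ~20% in-plane (551 x 701 x T at
the detector's 0.79 width-to-height aspect).  Here the same operations are
exposed at any scale: nearest-neighbour resampling for categorical masks,
local mean pooling for reconstructed intensities, and zero (air) padding
to the reconstruction extent.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .phantom import AIR, LabelVolume
from .reconstructor import ReconVolume

FULL_SCALE_SHAPE = (551, 701)   # in-plane reference of the full-scale study


@dataclass
class Sample:
    """One training/evaluation pair on congruent grids."""

    recon: ReconVolume
    mask: LabelVolume
    phantom_id: int
    geometry_name: str

    def __post_init__(self) -> None:
        if self.recon.shape != self.mask.shape:
            raise ValueError("recon and mask must be congruent")
        if abs(self.recon.voxel_mm - self.mask.voxel_mm) > 1e-9:
            raise ValueError("recon and mask pitches differ")

    @property
    def thickness_slices(self) -> int:
        return self.mask.shape[2]


def resample_mask(mask: LabelVolume, target_pitch_mm: float,
                  pad_to_shape: tuple[int, int, int] | None = None) -> LabelVolume:
    """Nearest-neighbour resampling of a label volume to a new pitch.

    Labels stay categorical; equal pitches return a bit-identical copy.
    ``pad_to_shape`` additionally zero-pads (air) up to a target extent.
    """
    if target_pitch_mm <= 0:
        raise ValueError("target pitch must be positive")
    labels = mask.labels
    if abs(target_pitch_mm - mask.voxel_mm) > 1e-12:
        new_shape = tuple(
            max(1, int(round(s * mask.voxel_mm / target_pitch_mm)))
            for s in labels.shape
        )
        idx = [
            np.clip(
                np.floor((np.arange(n) + 0.5) * target_pitch_mm / mask.voxel_mm),
                0, old - 1,
            ).astype(np.int64)
            for n, old in zip(new_shape, labels.shape)
        ]
        labels = labels[np.ix_(*idx)]
    else:
        labels = labels.copy()
    if pad_to_shape is not None:
        pads = [(0, max(0, t - s)) for t, s in zip(pad_to_shape, labels.shape)]
        labels = np.pad(labels, pads, constant_values=AIR)
        labels = labels[tuple(slice(0, t) for t in pad_to_shape)]
    return LabelVolume(labels=labels, voxel_mm=target_pitch_mm)


def _pool_shape(shape: tuple[int, ...], block: int) -> tuple[int, ...]:
    return tuple(s // block for s in shape)


def downsample(sample: Sample, factor: float = 0.2) -> Sample:
    """Downsample a sample by local mean pooling (recon) and
    nearest-neighbour block centres (mask).

    ``factor`` ~ 0.2 reproduces the full-scale pipeline's ~20% resize; the
    pooling block is ``round(1/factor)`` voxels per axis, so the in-plane
    aspect ratio is preserved.  ``factor = 1`` is the identity.
    """
    if not (0 < factor <= 1):
        raise ValueError("factor must lie in (0, 1]")
    block = int(round(1.0 / factor))
    if block == 1:
        return Sample(recon=sample.recon, mask=sample.mask,
                      phantom_id=sample.phantom_id,
                      geometry_name=sample.geometry_name)
    new_shape = _pool_shape(sample.recon.shape, block)
    if min(new_shape) < 8:
        raise ValueError("downsampled volume would be smaller than 8 voxels")
    crop = tuple(slice(0, s * block) for s in new_shape)
    vals = sample.recon.values[crop]
    nx, ny, nz = new_shape
    vals = vals.reshape(nx, block, ny, block, nz, block).mean(axis=(1, 3, 5))
    c = block // 2
    labels = sample.mask.labels[crop][c::block, c::block, c::block]
    labels = labels[:nx, :ny, :nz]
    pitch = sample.recon.voxel_mm * block
    return Sample(
        recon=ReconVolume(values=vals.astype(np.float32), voxel_mm=pitch),
        mask=LabelVolume(labels=labels, voxel_mm=pitch),
        phantom_id=sample.phantom_id,
        geometry_name=sample.geometry_name,
    )


def save_samples(samples: list[Sample], out_dir) -> pd.DataFrame:
    """Write paired NIfTI volumes + a CSV manifest; returns the manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in samples:
        stem = f"phantom{s.phantom_id:03d}_{s.geometry_name}"
        s.recon.save(out_dir / f"{stem}_recon.nii.gz")
        s.mask.save(out_dir / f"{stem}_mask.nii.gz")
        rows.append({
            "phantom_id": s.phantom_id,
            "geometry": s.geometry_name,
            "shape_x": s.recon.shape[0],
            "shape_y": s.recon.shape[1],
            "shape_z": s.recon.shape[2],
            "voxel_mm": s.recon.voxel_mm,
        })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
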