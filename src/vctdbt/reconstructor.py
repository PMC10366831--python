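"""Unfiltered simple backprojection onto a voxel grid.

Simple backprojection deliberately applies no filtering: each voxel
receives the mean, over sources, of the bilinearly interpolated detector
value where the source-voxel ray meets the detector plane.  The absence of
filtering preserves the limited-angle artifacts this tool studies — the
out-of-plane smear of tissue and the false boundaries in the convex-hull
region of the breast outline.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np

from .geometry import AcquisitionGeometry
from .projector import ProjectionSet


@dataclass
class ReconVolume:
    """Mean backprojected line integral per voxel, on the phantom frame."""

    values: np.ndarray            # (nx, ny, nz) float32
    voxel_mm: float
    coverage: np.ndarray | None = None   # projections covering each voxel

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 3:
            raise ValueError("values must be 3D")
        if not np.isfinite(self.values).all():
            raise ValueError("reconstruction contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def origin_mm(self) -> np.ndarray:
        nx = self.values.shape[0]
        return np.array([-0.5 * nx * self.voxel_mm, 0.0, 0.0])

    def save(self, path) -> None:
        affine = np.diag([self.voxel_mm] * 3 + [1.0])
        affine[:3, 3] = self.origin_mm()
        nib.save(nib.Nifti1Image(self.values.astype(np.float32), affine),
                 str(path))

    @classmethod
    def load(cls, path) -> "ReconVolume":
        img = nib.load(str(path))
        return cls(values=np.asarray(img.dataobj, dtype=np.float32),
                   voxel_mm=float(img.header.get_zooms()[0]))


def backproject(p: ProjectionSet, geometry: AcquisitionGeometry | None = None,
                grid_shape: tuple[int, int, int] | None = None,
                voxel_mm: float = 1.0) -> ReconVolume:
    """Voxel-driven simple backprojection of a projection set.

    For each source the ray through every voxel centre is intersected with
    the detector plane and the projection image is sampled bilinearly; the
    voxel value is the mean over the sources whose detector contains the
    intersection.  Voxels seen by no source are 0 and flagged in the
    coverage mask.
    """
    geometry = geometry or p.geometry
    if p.images.shape[0] != geometry.n_sources:
        raise ValueError("one image per source required")
    if grid_shape is None:
        raise ValueError("grid_shape is required")
    nx, ny, nz = grid_shape
    det = geometry.detector
    pitch, gap = det.pixel_pitch_mm, det.gap_mm

    x = (np.arange(nx) + 0.5 - 0.5 * nx) * voxel_mm
    y = (np.arange(ny) + 0.5) * voxel_mm
    z = (np.arange(nz) + 0.5) * voxel_mm

    acc = np.zeros((nx, ny, nz), dtype=np.float64)
    count = np.zeros((nx, ny, nz), dtype=np.int32)

    for s_idx in range(geometry.n_sources):
        sx, sy, sz = geometry.sources[s_idx]
        img = p.images[s_idx]
        t = (-gap - sz) / (z - sz)                       # (nz,)
        ux = sx + t[None, :] * (x[:, None] - sx)         # (nx, nz)
        vy = sy + t[None, :] * (y[:, None] - sy)         # (ny, nz)
        iu = ux / pitch + 0.5 * det.n_u - 0.5            # continuous index
        iv = vy / pitch - 0.5

        # half-pixel tolerance at the edges: nearest-pixel extrapolation
        ok_u = (iu >= -0.5) & (iu <= det.n_u - 0.5)      # (nx, nz)
        ok_v = (iv >= -0.5) & (iv <= det.n_v - 0.5)      # (ny, nz)
        iu = np.clip(iu, 0, det.n_u - 1)
        iv = np.clip(iv, 0, det.n_v - 1)
        fu = np.floor(iu).astype(np.int64)
        fv = np.floor(iv).astype(np.int64)
        wu = iu - fu
        wv = iv - fv
        fu0 = np.clip(fu, 0, det.n_u - 1)
        fu1 = np.clip(fu + 1, 0, det.n_u - 1)
        fv0 = np.clip(fv, 0, det.n_v - 1)
        fv1 = np.clip(fv + 1, 0, det.n_v - 1)

        for k in range(nz):
            cov = ok_u[:, k][:, None] & ok_v[:, k][None, :]
            if not cov.any():
                continue
            a0, a1 = fu0[:, k], fu1[:, k]
            b0, b1 = fv0[:, k], fv1[:, k]
            w_u = wu[:, k][:, None]
            w_v = wv[:, k][None, :]
            val = ((1 - w_u) * (1 - w_v) * img[a0[:, None], b0[None, :]]
                   + w_u * (1 - w_v) * img[a1[:, None], b0[None, :]]
                   + (1 - w_u) * w_v * img[a0[:, None], b1[None, :]]
                   + w_u * w_v * img[a1[:, None], b1[None, :]])
            acc[:, :, k] += np.where(cov, val, 0.0)
            count[:, :, k] += cov

    values = np.divide(acc, count, out=np.zeros_like(acc),
                       where=count > 0)
    return ReconVolume(values=values.astype(np.float32), voxel_mm=voxel_mm,
                       coverage=count)


def threshold_segment(recon: ReconVolume,
                      threshold: float | None = None) -> "LabelVolume":
    """Air/tissue segmentation of a reconstruction by global thresholding.

    Voxels above the threshold (Otsu's method by default) are labelled
    adipose tissue, the rest air.  This model-free segmentation exposes the
    convex-hull artifact: backprojected tissue signal smeared into the air
    gap between the curved breast surface and the paddle/support is
    misclassified as tissue.
    """
    from skimage.filters import threshold_otsu

    from .phantom import ADIPOSE, LabelVolume

    if threshold is None:
        threshold = float(threshold_otsu(recon.values))
    labels = np.where(recon.values > threshold, ADIPOSE, 0).astype(np.uint8)
    return LabelVolume(labels=labels, voxel_mm=recon.voxel_mm)


def zpsf_width(recon: ReconVolume) -> float:
    """Full width at half maximum (mm) of the z-profile through the peak.

    Quantifies the out-of-plane spread of a point-like object: the wider
    the tomographic angle, the narrower this profile.
    """
    v = recon.values
    if v.max() <= v.min():
        raise ValueError("flat reconstruction: no peak to measure")
    ix, iy, iz = np.unravel_index(int(np.argmax(v)), v.shape)
    prof = v[ix, iy, :].astype(np.float64)
    half = prof[iz] / 2.0

    def _cross(idx_range) -> float:
        idx = list(idx_range)
        if not idx:
            return float(iz)
        prev = iz
        for k in idx:
            if prof[k] < half:
                # linear interpolation between k and the previous index
                frac = (prof[prev] - half) / (prof[prev] - prof[k])
                return prev + frac * (k - prev)
            prev = k
        return float(idx[-1])

    left = _cross(range(iz - 1, -1, -1))
    right = _cross(range(iz + 1, len(prof)))
    return abs(right - left) * recon.voxel_mm
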