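"""Voxelized compressed-breast phantoms.

A phantom is a three-class label volume (air / adipose / dense tissue) on an
isotropic grid.  The breast outline models craniocaudal compression: flat
bands in contact with the compression paddle (top) and breast support
(bottom), joined by a curved free surface ("convex hull") that bulges
outward at mid-thickness.  Internal composition is an octree block fill that
matches a target volumetric breast density (%VBD).

Axes convention (shared by every module):

* axis 0, ``x`` — left-right (the conventional tube-travel direction),
  centred on the volume;
* axis 1, ``y`` — posteroanterior, chest wall at ``y = 0``;
* axis 2, ``z`` — vertical, breast support at ``z = 0``, paddle at
  ``z = CBT``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import nibabel as nib
import numpy as np
import pandas as pd

AIR, ADIPOSE, DENSE = 0, 1, 2

# z-score of the 1st/3rd quartile of a standard normal
_Z75 = 0.6744897501960817


@dataclass(frozen=True)
class PopulationSpec:
    """Sampling specification of a screening population.

    Compressed breast thickness (CBT) and volumetric breast density (%VBD)
    are summarised clinically by median and interquartile values; samples
    are drawn from log-normal distributions calibrated to those statistics,
    and CBT is capped (default 85 mm, the upper limit of the compression
    model).
    """

    n_phantoms: int = 10
    cbt_median_mm: float = 60.50
    cbt_q1_mm: float = 51.50
    cbt_q3_mm: float = 69.50
    vbd_median_pct: float = 12.75
    vbd_q1_pct: float = 8.40
    vbd_q3_pct: float = 20.00
    cbt_cap_mm: float = 85.0
    voxel_mm: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_phantoms < 1:
            raise ValueError("n_phantoms must be >= 1")
        for lo, mid, hi, name in (
            (self.cbt_q1_mm, self.cbt_median_mm, self.cbt_q3_mm, "CBT"),
            (self.vbd_q1_pct, self.vbd_median_pct, self.vbd_q3_pct, "VBD"),
        ):
            if not (lo < mid < hi):
                raise ValueError(
                    f"{name} quartiles must satisfy q1 < median < q3, "
                    f"got ({lo}, {mid}, {hi})"
                )
        if self.voxel_mm <= 0:
            raise ValueError("voxel_mm must be positive")


@dataclass(frozen=True)
class OutlineParams:
    """Geometric parameters of one compressed-breast outline.

    ``contact_fraction`` is the fraction of the thickness in flat contact
    with paddle + support (split evenly); between the contact bands the
    footprint grows by up to ``bulge_mm`` following a superelliptic profile
    with exponent ``curvature_exponent``.
    """

    cbt_mm: float
    cnd_mm: float
    width_mm: float
    contact_fraction: float = 0.4
    bulge_mm: float = 6.0
    curvature_exponent: float = 4.0

    def __post_init__(self) -> None:
        if not (0 < self.contact_fraction <= 1):
            raise ValueError("contact_fraction must lie in (0, 1]")
        if self.bulge_mm < 0:
            raise ValueError("bulge_mm must be >= 0")
        if min(self.cbt_mm, self.cnd_mm, self.width_mm) <= 0:
            raise ValueError("cbt_mm, cnd_mm, width_mm must be positive")
        if self.curvature_exponent <= 0:
            raise ValueError("curvature_exponent must be positive")


@dataclass
class LabelVolume:
    """Three-class voxel volume: 0 = air, 1 = adipose, 2 = dense tissue."""

    labels: np.ndarray  # uint8, shape (nx, ny, nz)
    voxel_mm: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D array")
        if not np.isin(self.labels, (AIR, ADIPOSE, DENSE)).all():
            raise ValueError("labels must take values in {0, 1, 2}")
        self.labels = self.labels.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def origin_mm(self) -> np.ndarray:
        """World position of the voxel-grid corner (x centred, y and z at 0)."""
        nx = self.labels.shape[0]
        return np.array([-0.5 * nx * self.voxel_mm, 0.0, 0.0])

    def save(self, path) -> None:
        affine = np.diag([self.voxel_mm] * 3 + [1.0])
        affine[:3, 3] = self.origin_mm()
        nib.save(nib.Nifti1Image(self.labels, affine), str(path))

    @classmethod
    def load(cls, path) -> "LabelVolume":
        img = nib.load(str(path))
        voxel = float(img.header.get_zooms()[0])
        return cls(labels=np.asarray(img.dataobj).astype(np.uint8), voxel_mm=voxel)


@dataclass(frozen=True)
class PhantomParams:
    """One sampled member of the population."""

    phantom_id: int
    outline: OutlineParams
    target_vbd: float           # fraction in (0, 1)
    cbt_raw_mm: float           # thickness sample before the cap
    seed: int                   # per-phantom fill seed


def _lognormal_params(median: float, q1: float, q3: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal matching the median and the IQR ratio."""
    return np.log(median), np.log(q3 / q1) / (2.0 * _Z75)


def sample_population(spec: PopulationSpec) -> list[PhantomParams]:
    """Draw outline parameters and density targets for ``spec.n_phantoms``.

    CBT and %VBD are sampled from log-normals calibrated to the spec's
    median/IQR; CBT is then capped at ``cbt_cap_mm``.  Secondary outline
    parameters (chest-to-nipple distance, width, bulge) scale with CBT with
    mild per-phantom jitter.  Deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    mu_c, sg_c = _lognormal_params(spec.cbt_median_mm, spec.cbt_q1_mm, spec.cbt_q3_mm)
    mu_v, sg_v = _lognormal_params(spec.vbd_median_pct, spec.vbd_q1_pct, spec.vbd_q3_pct)

    out: list[PhantomParams] = []
    for i in range(spec.n_phantoms):
        cbt_raw = float(rng.lognormal(mu_c, sg_c))
        cbt = min(cbt_raw, spec.cbt_cap_mm)
        vbd = float(np.clip(rng.lognormal(mu_v, sg_v) / 100.0, 1e-3, 0.75))
        # secondary geometry: CND ~ 1.75 CBT, width ~ 2.2 CBT (Fig-2-like
        # proportions), bulge ~ 10% CBT; jitter keeps phantoms distinct
        cnd = cbt * rng.uniform(1.6, 1.9)
        width = cbt * rng.uniform(2.0, 2.4)
        bulge = cbt * rng.uniform(0.08, 0.14)
        contact = rng.uniform(0.35, 0.5)
        expo = rng.uniform(3.0, 5.0)
        out.append(
            PhantomParams(
                phantom_id=i,
                outline=OutlineParams(
                    cbt_mm=cbt, cnd_mm=cnd, width_mm=width,
                    contact_fraction=contact, bulge_mm=bulge,
                    curvature_exponent=expo,
                ),
                target_vbd=vbd,
                cbt_raw_mm=cbt_raw,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return out


def _bulge_profile(z_mm: np.ndarray, p: OutlineParams) -> np.ndarray:
    """Normalised outward bulge g(z) in [0, 1]: 0 in the contact bands,
    1 at mid-thickness, superelliptic in between."""
    band = 0.5 * p.contact_fraction * p.cbt_mm  # per-side flat band
    z_mid = 0.5 * p.cbt_mm
    half_free = max(z_mid - band, 1e-9)
    u = np.clip(np.abs(z_mm - z_mid) / half_free, 0.0, 1.0)
    k = p.curvature_exponent
    return (1.0 - u**k) ** (1.0 / k)


def generate_outline(p: OutlineParams, voxel_mm: float,
                     grid_shape: tuple[int, int, int] | None = None) -> np.ndarray:
    """Binary tissue mask of a compressed breast outline.

    Every z-slice footprint is the half-ellipse ``(x/a)^2 + (y/b)^2 <= 1``
    with ``y >= 0`` (attached to the chest wall); the semi-axes grow from
    their contact-band values by ``bulge_mm * g(z)``, so the footprint is
    maximal at mid-thickness and shrinks monotonically toward paddle and
    support.
    """
    nz_breast = int(round(p.cbt_mm / voxel_mm))
    if nz_breast < 3:
        raise ValueError("cbt_mm must span at least 3 voxels")
    if grid_shape is None:
        nx = int(np.ceil((p.width_mm + 2 * p.bulge_mm) / voxel_mm)) + 2
        ny = int(np.ceil((p.cnd_mm + p.bulge_mm) / voxel_mm)) + 2
        grid_shape = (nx, ny, nz_breast)
    nx, ny, nz = grid_shape

    x = (np.arange(nx) + 0.5 - 0.5 * nx) * voxel_mm
    y = (np.arange(ny) + 0.5) * voxel_mm
    z = (np.arange(nz) + 0.5) * voxel_mm

    g = np.where(z <= p.cbt_mm, _bulge_profile(z, p), 0.0)
    a = 0.5 * p.width_mm + p.bulge_mm * g   # (nz,) LR semi-axis
    b = p.cnd_mm + p.bulge_mm * g           # (nz,) PA extent
    inside = (
        (x[:, None, None] / a[None, None, :]) ** 2
        + (y[None, :, None] / b[None, None, :]) ** 2
    ) <= 1.0
    inside &= z[None, None, :] <= p.cbt_mm
    return inside


def measure_vbd(v: LabelVolume | np.ndarray) -> float:
    """Dense fraction of the tissue: dense / (dense + adipose)."""
    labels = v.labels if isinstance(v, LabelVolume) else np.asarray(v)
    dense = int((labels == DENSE).sum())
    adipose = int((labels == ADIPOSE).sum())
    if dense + adipose == 0:
        raise ValueError("volume contains no tissue voxels")
    return dense / (dense + adipose)


def fill_tissue(mask: np.ndarray, target_vbd: float, min_block_mm: float,
                seed: int, voxel_mm: float,
                tol: float = 0.005,
                max_block_mm: float | None = None) -> LabelVolume:
    """Assign dense tissue inside ``mask`` by recursive octree block fill.

    The tissue bounding box is subdivided into octants down to
    ``min_block_mm``; whole blocks no larger than ``max_block_mm`` (default
    8x the minimum) are switched to dense, in a seeded random order, until
    the achieved dense fraction is within ``tol`` (default 0.5 percentage
    points) of ``target_vbd``.  Blocks whose inclusion would overshoot past
    ``target + tol`` are split further instead.  If the target is
    unreachable at the block granularity the closest achievable fill is
    kept and a warning is emitted.
    """
    if not (0 <= target_vbd < 1):
        raise ValueError("target_vbd must lie in [0, 1)")
    mask = np.asarray(mask, dtype=bool)
    labels = np.where(mask, ADIPOSE, AIR).astype(np.uint8)
    n_tissue = int(mask.sum())
    if n_tissue == 0:
        raise ValueError("mask contains no tissue voxels")
    target_count = target_vbd * n_tissue
    if target_count < 0.5:  # below one voxel: all adipose
        return LabelVolume(labels=labels, voxel_mm=voxel_mm)

    rng = np.random.default_rng(seed)
    min_block_vox = max(1, int(round(min_block_mm / voxel_mm)))
    if max_block_mm is None:
        max_block_mm = 8.0 * min_block_mm
    max_block_vox = max(min_block_vox, int(round(max_block_mm / voxel_mm)))
    idx = np.argwhere(mask)
    lo, hi = idx.min(axis=0), idx.max(axis=0) + 1

    dense_count = 0
    tol_count = tol * n_tissue
    # stack of octree nodes (x0, x1, y0, y1, z0, z1), seeded random order
    stack: list[tuple[int, int, int, int, int, int]] = [
        (lo[0], hi[0], lo[1], hi[1], lo[2], hi[2])
    ]
    while stack and dense_count < target_count - 0.5:
        node = stack.pop(int(rng.integers(len(stack))))
        x0, x1, y0, y1, z0, z1 = node
        block_tissue = mask[x0:x1, y0:y1, z0:z1] & (
            labels[x0:x1, y0:y1, z0:z1] == ADIPOSE
        )
        n_block = int(block_tissue.sum())
        if n_block == 0:
            continue
        small_enough = max(x1 - x0, y1 - y0, z1 - z0) <= max_block_vox
        if small_enough and dense_count + n_block <= target_count + tol_count:
            sub = labels[x0:x1, y0:y1, z0:z1]
            sub[block_tissue] = DENSE
            dense_count += n_block
            continue
        # block too large: subdivide octants unless at minimum granularity
        if max(x1 - x0, y1 - y0, z1 - z0) <= min_block_vox:
            continue
        xm, ym, zm = (x0 + x1) // 2, (y0 + y1) // 2, (z0 + z1) // 2
        for cx0, cx1 in ((x0, xm), (xm, x1)):
            for cy0, cy1 in ((y0, ym), (ym, y1)):
                for cz0, cz1 in ((z0, zm), (zm, z1)):
                    if cx1 > cx0 and cy1 > cy0 and cz1 > cz0:
                        stack.append((cx0, cx1, cy0, cy1, cz0, cz1))

    achieved = dense_count / n_tissue
    if abs(achieved - target_vbd) > tol:
        warnings.warn(
            f"target VBD {target_vbd:.4f} unreachable at block granularity; "
            f"achieved {achieved:.4f}",
            stacklevel=2,
        )
    return LabelVolume(labels=labels, voxel_mm=voxel_mm)


def build_phantom(params: PhantomParams, voxel_mm: float,
                  min_block_mm: float | None = None,
                  grid_shape: tuple[int, int, int] | None = None) -> LabelVolume:
    """Outline + octree fill for one sampled phantom."""
    if min_block_mm is None:
        min_block_mm = 2.0 * voxel_mm
    mask = generate_outline(params.outline, voxel_mm, grid_shape=grid_shape)
    return fill_tissue(mask, params.target_vbd, min_block_mm,
                       params.seed, voxel_mm)


def population_manifest(params: list[PhantomParams],
                        volumes: list[LabelVolume] | None = None) -> pd.DataFrame:
    """Tabular manifest of a simulated population (one row per phantom)."""
    rows = []
    for i, p in enumerate(params):
        row = {
            "phantom_id": p.phantom_id,
            "cbt_mm": p.outline.cbt_mm,
            "cbt_raw_mm": p.cbt_raw_mm,
            "cnd_mm": p.outline.cnd_mm,
            "target_vbd": p.target_vbd,
            "seed": p.seed,
        }
        if volumes is not None:
            row["achieved_vbd"] = measure_vbd(volumes[i])
        rows.append(row)
    return pd.DataFrame(rows)
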