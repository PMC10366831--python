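"""Acquisition geometries of the next-generation tomosynthesis (NGT) system.

Three scan geometries are modelled as explicit ordered source trajectories
above the compressed breast:

* **conventional** (I): 15 source positions on a left-right (LR) line
  spanning an angular range of +/-7.5 degrees;
* **T** (II): a bidirectional scan — an 8-point LR leg plus a 7-point
  posteroanterior (PA) leg, 15 positions in total;
* **XWR** (III): 91 positions on a circular arc of radius 738 mm pivoting
  at the breast support, spanning +/-45 degrees, at 6x the total exposure.

The detector is a flat plane a small gap below the breast support, with the
clinical width-to-height pixel-count ratio of 0.79.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

DEFAULT_SID_MM = 620.0  # source-to-support distance of the linear scans


@dataclass(frozen=True)
class DetectorSpec:
    """Flat detector in the plane ``z = -gap_mm``.

    ``u`` indexes the LR axis (x), ``v`` the PA axis (y, from the chest
    wall).  ``n_u / n_v`` keeps the 0.79 width-to-height aspect.
    """

    pixel_pitch_mm: float = 2.0
    n_u: int = 44
    n_v: int = 56
    gap_mm: float = 25.0

    def __post_init__(self) -> None:
        if self.pixel_pitch_mm <= 0:
            raise ValueError("pixel_pitch_mm must be positive")
        if self.n_u < 1 or self.n_v < 1:
            raise ValueError("detector pixel counts must be >= 1")

    @property
    def aspect(self) -> float:
        return self.n_u / self.n_v

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """World (x, y) coordinates of pixel centres; z is ``-gap_mm``."""
        u = (np.arange(self.n_u) + 0.5 - 0.5 * self.n_u) * self.pixel_pitch_mm
        v = (np.arange(self.n_v) + 0.5) * self.pixel_pitch_mm
        return u, v

    @property
    def center_y(self) -> float:
        """Default source y: above the chest wall (v = 0 edge), as in
        clinical craniocaudal positioning."""
        return 0.0


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Ordered source positions + detector + relative exposure."""

    name: str
    sources: np.ndarray          # (n, 3) world mm
    motion: str                  # linear_LR | linear_T | arc_LR
    sid_mm: float
    exposure_scale: float
    detector: DetectorSpec

    def __post_init__(self) -> None:
        src = np.asarray(self.sources, dtype=float)
        if src.ndim != 2 or src.shape[1] != 3 or src.shape[0] < 1:
            raise ValueError("sources must be an (n, 3) array with n >= 1")
        if self.exposure_scale <= 0:
            raise ValueError("exposure_scale must be positive")
        object.__setattr__(self, "sources", src)

    @property
    def n_sources(self) -> int:
        return self.sources.shape[0]

    def to_json(self, path=None) -> str:
        d = {
            "name": self.name,
            "sources": self.sources.tolist(),
            "motion": self.motion,
            "sid_mm": self.sid_mm,
            "exposure_scale": self.exposure_scale,
            "detector": asdict(self.detector),
        }
        text = json.dumps(d, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "AcquisitionGeometry":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            d = json.loads(source)
        else:
            with open(source) as fh:
                d = json.load(fh)
        return cls(
            name=d["name"],
            sources=np.asarray(d["sources"], dtype=float),
            motion=d["motion"],
            sid_mm=float(d["sid_mm"]),
            exposure_scale=float(d["exposure_scale"]),
            detector=DetectorSpec(**d["detector"]),
        )


def _lr_positions(n: int, half_angle_deg: float, sid_mm: float,
                  center_y: float) -> np.ndarray:
    """n sources on an LR line at height sid, spanning +/-half_angle."""
    half_extent = sid_mm * np.tan(np.deg2rad(half_angle_deg))
    x = np.linspace(-half_extent, half_extent, n) if n > 1 else np.array([0.0])
    return np.column_stack([x, np.full(n, center_y), np.full(n, sid_mm)])


def make_conventional(n: int = 15, half_angle_deg: float = 7.5,
                      sid_mm: float = DEFAULT_SID_MM,
                      detector: DetectorSpec | None = None,
                      center_y: float | None = None) -> AcquisitionGeometry:
    """Conventional geometry (I): unidirectional LR scan, AEC exposure."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if half_angle_deg <= 0:
        raise ValueError("half_angle_deg must be positive")
    detector = detector or DetectorSpec()
    cy = detector.center_y if center_y is None else center_y
    return AcquisitionGeometry(
        name="conventional",
        sources=_lr_positions(n, half_angle_deg, sid_mm, cy),
        motion="linear_LR",
        sid_mm=sid_mm,
        exposure_scale=1.0,
        detector=detector,
    )


def make_t(n_pa: int = 7, n_lr: int = 8, half_angle_deg: float = 7.5,
           sid_mm: float = DEFAULT_SID_MM,
           detector: DetectorSpec | None = None,
           center_y: float | None = None) -> AcquisitionGeometry:
    """T geometry (II): LR leg (8 sources) then PA leg (7 sources).

    The LR bar sits above the chest wall; the PA stem extends from the
    bar's centre over the breast toward the nipple (the tube cannot
    travel behind the patient), covering the same total angular span as
    the LR leg.
    """
    if n_pa < 1 or n_lr < 1:
        raise ValueError("both T legs need at least one source")
    detector = detector or DetectorSpec()
    cy = detector.center_y if center_y is None else center_y
    lr = _lr_positions(n_lr, half_angle_deg, sid_mm, cy)
    full_extent = 2.0 * sid_mm * np.tan(np.deg2rad(half_angle_deg))
    y = cy + (np.linspace(0.0, full_extent, n_pa)
              if n_pa > 1 else np.array([0.0]))
    pa = np.column_stack([np.zeros(n_pa), y, np.full(n_pa, sid_mm)])
    return AcquisitionGeometry(
        name="T",
        sources=np.vstack([lr, pa]),
        motion="linear_T",
        sid_mm=sid_mm,
        exposure_scale=1.0,
        detector=detector,
    )


def make_xwr(n: int = 91, half_angle_deg: float = 45.0,
             radius_mm: float = 738.0,
             detector: DetectorSpec | None = None,
             center_y: float | None = None) -> AcquisitionGeometry:
    """XWR geometry (III): arc scan, pivot at the breast support, 6x AEC.

    Sources lie on a circle of radius 738 mm in the x-z plane, pivoting at
    the support-plane centre, at equally spaced angles over +/-45 degrees.
    """
    if n < 2:
        raise ValueError("n must be >= 2 for an arc")
    detector = detector or DetectorSpec()
    if radius_mm <= 0:
        raise ValueError("radius_mm must be positive")
    cy = detector.center_y if center_y is None else center_y
    phi = np.deg2rad(np.linspace(-half_angle_deg, half_angle_deg, n))
    sources = np.column_stack([
        radius_mm * np.sin(phi),
        np.full(n, cy),
        radius_mm * np.cos(phi),
    ])
    return AcquisitionGeometry(
        name="XWR",
        sources=sources,
        motion="arc_LR",
        sid_mm=radius_mm,
        exposure_scale=6.0,
        detector=detector,
    )


def make_geometry(kind: str, detector: DetectorSpec | None = None,
                  **kwargs) -> AcquisitionGeometry:
    """Factory by name: 'conventional' | 't' | 'xwr'."""
    kind = kind.lower()
    if kind in ("conventional", "i"):
        return make_conventional(detector=detector, **kwargs)
    if kind in ("t", "ii"):
        return make_t(detector=detector, **kwargs)
    if kind in ("xwr", "iii"):
        return make_xwr(detector=detector, **kwargs)
    raise ValueError(f"unknown geometry kind: {kind!r}")
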