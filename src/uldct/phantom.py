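"""Synthetic pelvic CT phantom with known tissues, noise and hip geometry.

The phantom stands in for patient scans: a soft-tissue body (ellipsoid trunk
plus two proximal-thigh cylinders) in an air background, two femoral heads
(solid cortical spheres), femoral shafts with a cortical wall around a
trabecular core, and small cortical marker spheres at the lateral acetabular
rim and the inferior teardrop of each hip. Because every tissue HU, the
noise level and the hip angles are configured, each downstream stage
(projection, ROI statistics, angle measurement, agreement) can be tested
against exact ground truth.

All hip landmarks are placed in a single coronal plane (constant y) through
the projection target, so a cone-beam projection whose detector is parallel
to that plane magnifies the landmark constellation uniformly and preserves
the configured angles.

Tissue classes are composited last-writer-wins in a fixed order:
background air → soft tissue → trabecular bone → cortical bone.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import ArgumentError, GeometryError
from .volume import CTVolume

__all__ = [
    "HipSide",
    "PhantomSpec",
    "GroundTruth",
    "build_phantom",
    "add_noise",
    "default_rois",
    "load_ground_truth",
]

LABELS = ("air", "muscle", "trabecular", "cortical")
_SIDE_SIGN = {"left": 1.0, "right": -1.0}  # +x is patient left (LPS)


@dataclass
class HipSide:
    """One hip joint: femoral head plus configured ground-truth angles."""

    head_center_mm: tuple[float, float, float]
    head_radius_mm: float = 24.0
    ce_angle_deg: float = 30.0
    sharp_angle_deg: float = 40.0


@dataclass
class PhantomSpec:
    """Parameters of the synthetic pelvic volume.

    HU anchors default to air −1000, muscle 55, trabecular 300 and cortical
    1300; all are configurable. ``sides`` maps ``"left"``/``"right"`` to
    :class:`HipSide`; an empty mapping (with ``include_body=False``) yields a
    pure-air scene.
    """

    volume_shape: tuple[int, int, int] = (180, 120, 110)
    spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    hu_air: float = -1000.0
    hu_muscle: float = 55.0
    hu_trabecular: float = 300.0
    hu_cortical: float = 1300.0
    sides: dict = field(default_factory=dict)
    include_body: bool = True
    include_shafts: bool = True
    include_markers: bool = True
    body_center_mm: tuple[float, float, float] = (0.0, 20.0, 0.0)
    body_semiaxes_mm: tuple[float, float, float] = (150.0, 80.0, 100.0)
    leg_radius_mm: float = 45.0
    rim_offset_mm: float = 6.0
    marker_radius_mm: float = 4.0
    teardrop_rim_distance_mm: float = 55.0
    shaft_outer_radius_mm: float = 16.0
    shaft_core_radius_mm: float = 8.0
    shaft_length_mm: float = 40.0
    noise_sd_hu: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.sides:
            self.sides = {}

    @classmethod
    def default_bilateral(cls, **overrides) -> "PhantomSpec":
        """Spec with both hips at the default pelvic geometry."""
        sides = {
            "left": HipSide(head_center_mm=(90.0, 0.0, -40.0)),
            "right": HipSide(head_center_mm=(-90.0, 0.0, -40.0)),
        }
        return cls(sides=sides, **overrides)

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        sides = {}
        for name, s in (d.pop("sides", {}) or {}).items():
            sides[name] = HipSide(
                head_center_mm=tuple(s["head_center_mm"]),
                head_radius_mm=float(s.get("head_radius_mm", 24.0)),
                ce_angle_deg=float(s.get("ce_angle_deg", 30.0)),
                sharp_angle_deg=float(s.get("sharp_angle_deg", 40.0)),
            )
        for key in ("volume_shape", "spacing_mm", "body_center_mm", "body_semiaxes_mm"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(sides=sides, **d)

    @classmethod
    def from_file(cls, path) -> "PhantomSpec":
        path = Path(path)
        with open(path) as fh:
            data = yaml.safe_load(fh) if path.suffix in (".yml", ".yaml") else json.load(fh)
        return cls.from_dict(data)

    def validate(self) -> None:
        if any(s <= 0 for s in self.spacing_mm):
            raise ArgumentError("spacing must be positive")
        if self.noise_sd_hu < 0:
            raise ArgumentError("noise SD must be non-negative")
        if not (self.hu_air < self.hu_muscle < self.hu_trabecular < self.hu_cortical):
            raise ArgumentError("tissue HU must be ordered air < muscle < trabecular < cortical")
        for name, side in self.sides.items():
            if name not in _SIDE_SIGN:
                raise ArgumentError(f"unknown side {name!r}")
            if side.head_radius_mm <= 0:
                raise ArgumentError("head radius must be positive")
            for ang in (side.ce_angle_deg, side.sharp_angle_deg):
                if not 0.0 <= ang <= 90.0:
                    raise ArgumentError(f"angles must lie in [0, 90] deg, got {ang}")
        if len(self.sides) == 2:
            cl = np.asarray(self.sides["left"].head_center_mm)
            cr = np.asarray(self.sides["right"].head_center_mm)
            min_gap = self.sides["left"].head_radius_mm + self.sides["right"].head_radius_mm
            if float(np.linalg.norm(cl - cr)) <= min_gap:
                raise GeometryError("left and right femoral heads overlap")


@dataclass
class GroundTruth:
    """Analytic truth for one phantom: landmark world coordinates (mm),
    configured CE/Sharp angles (deg), per-voxel tissue labels and the
    injected noise SD."""

    landmarks: dict
    head_radius_mm: dict
    ce_angle_deg: dict
    sharp_angle_deg: dict
    labels: np.ndarray
    noise_sd_hu: float
    coronal_plane_y_mm: float = 0.0

    def mask(self, tissue: str) -> np.ndarray:
        return self.labels == LABELS.index(tissue)

    def equator_points(self, side: str, n: int = 24) -> np.ndarray:
        """World points on the femoral-head equator circle in the landmark
        plane; projecting and circle-fitting them recovers the head center."""
        c = np.asarray(self.landmarks[side]["head_center"], dtype=float)
        r = self.head_radius_mm[side]
        t = np.linspace(0.0, 2.0 * math.pi, n, endpoint=False)
        pts = np.stack([c[0] + r * np.cos(t), np.full(n, c[1]), c[2] + r * np.sin(t)], axis=1)
        return pts

    def to_json(self, path) -> None:
        payload = {
            "landmarks": {s: {k: list(v) for k, v in lm.items()} for s, lm in self.landmarks.items()},
            "head_radius_mm": self.head_radius_mm,
            "ce_angle_deg": self.ce_angle_deg,
            "sharp_angle_deg": self.sharp_angle_deg,
            "noise_sd_hu": self.noise_sd_hu,
            "coronal_plane_y_mm": self.coronal_plane_y_mm,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)


def load_ground_truth(path) -> GroundTruth:
    """Load landmark/angle ground truth saved by :meth:`GroundTruth.to_json`
    (label volume is not round-tripped)."""
    with open(path) as fh:
        d = json.load(fh)
    return GroundTruth(
        landmarks={s: {k: tuple(v) for k, v in lm.items()} for s, lm in d["landmarks"].items()},
        head_radius_mm=d["head_radius_mm"],
        ce_angle_deg=d["ce_angle_deg"],
        sharp_angle_deg=d["sharp_angle_deg"],
        labels=np.zeros((2, 2, 2), dtype=np.uint8),
        noise_sd_hu=d["noise_sd_hu"],
        coronal_plane_y_mm=d["coronal_plane_y_mm"],
    )


def _hip_landmarks(spec: PhantomSpec, name: str, side: HipSide) -> dict:
    """Rim and teardrop placed so the configured CE and Sharp angles hold
    exactly in the coronal landmark plane."""
    sign = _SIDE_SIGN[name]
    c = np.asarray(side.head_center_mm, dtype=float)
    theta = math.radians(side.ce_angle_deg)
    d = side.head_radius_mm + spec.rim_offset_mm
    rim = c + d * np.array([sign * math.sin(theta), 0.0, math.cos(theta)])
    phi = math.radians(side.sharp_angle_deg)
    L = spec.teardrop_rim_distance_mm
    teardrop = rim - L * np.array([sign * math.cos(phi), 0.0, math.sin(phi)])
    return {"head_center": tuple(c), "rim": tuple(rim), "teardrop": tuple(teardrop)}


def build_phantom(spec: PhantomSpec) -> tuple[CTVolume, GroundTruth]:
    """Voxelize the phantom.

    The noiseless volume takes exactly the configured class HU values; the
    volume is centered on the world origin. Raises
    :class:`~uldct.errors.GeometryError` if any landmark falls outside the
    volume or the femoral heads overlap.
    """
    spec.validate()
    shape = tuple(int(n) for n in spec.volume_shape)
    sp = np.asarray(spec.spacing_mm, dtype=float)
    extent = np.asarray(shape) * sp
    origin = -extent / 2.0 + sp / 2.0  # voxel centers, volume centered on origin

    ax = [origin[a] + np.arange(shape[a]) * sp[a] for a in range(3)]
    x, y, z = np.meshgrid(*ax, indexing="ij", sparse=True)

    labels = np.zeros(shape, dtype=np.uint8)  # 0 = air

    landmarks = {name: _hip_landmarks(spec, name, side) for name, side in spec.sides.items()}
    lo = origin - sp / 2.0
    hi = origin + (np.asarray(shape) - 0.5) * sp
    for name, lm in landmarks.items():
        for key, pt in lm.items():
            p = np.asarray(pt)
            if np.any(p < lo) or np.any(p > hi):
                raise GeometryError(f"{name} {key} landmark {pt} outside volume bounds")

    # soft tissue: trunk ellipsoid + proximal thigh cylinders
    if spec.include_body:
        bc = np.asarray(spec.body_center_mm)
        bs = np.asarray(spec.body_semiaxes_mm)
        body = ((x - bc[0]) / bs[0]) ** 2 + ((y - bc[1]) / bs[1]) ** 2 + ((z - bc[2]) / bs[2]) ** 2 <= 1.0
        labels[body] = 1
        for name, side in spec.sides.items():
            cx, cy, _ = side.head_center_mm
            leg = ((x - cx) ** 2 + (y - cy) ** 2 <= spec.leg_radius_mm**2) & (z >= lo[2] + 2 * sp[2]) & (z <= 0.0)
            labels[np.broadcast_to(leg, shape)] = 1

    # femoral shafts: trabecular core inside a cortical wall
    for name, side in spec.sides.items():
        cx, cy, cz = side.head_center_mm
        if spec.include_shafts:
            z_top = cz - side.head_radius_mm - 2.0
            z_bot = z_top - spec.shaft_length_mm
            in_z = (z >= z_bot) & (z <= z_top)
            r2 = (x - cx) ** 2 + (y - cy) ** 2
            outer = (r2 <= spec.shaft_outer_radius_mm**2) & in_z
            labels[np.broadcast_to(outer, shape)] = 2  # whole shaft trabecular first
            wall = outer & (r2 > spec.shaft_core_radius_mm**2)
            labels[np.broadcast_to(wall, shape)] = 3

    # femoral heads: solid cortical spheres
    for name, side in spec.sides.items():
        cx, cy, cz = side.head_center_mm
        head = (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 < side.head_radius_mm**2
        labels[head] = 3

    # rim / teardrop cortical markers
    if spec.include_markers:
        for name, lm in landmarks.items():
            for key in ("rim", "teardrop"):
                p = np.asarray(lm[key])
                ball = (x - p[0]) ** 2 + (y - p[1]) ** 2 + (z - p[2]) ** 2 <= spec.marker_radius_mm**2
                labels[ball] = 3

    hu = np.array([spec.hu_air, spec.hu_muscle, spec.hu_trabecular, spec.hu_cortical], dtype=np.float32)
    values = hu[labels]

    volume = CTVolume(values, tuple(sp), tuple(origin))
    plane_y = next(iter(spec.sides.values())).head_center_mm[1] if spec.sides else 0.0
    gt = GroundTruth(
        landmarks=landmarks,
        head_radius_mm={n: s.head_radius_mm for n, s in spec.sides.items()},
        ce_angle_deg={n: float(s.ce_angle_deg) for n, s in spec.sides.items()},
        sharp_angle_deg={n: float(s.sharp_angle_deg) for n, s in spec.sides.items()},
        labels=labels,
        noise_sd_hu=spec.noise_sd_hu,
        coronal_plane_y_mm=float(plane_y),
    )
    return volume, gt


def add_noise(volume: CTVolume, sd_hu: float, seed: int | np.random.Generator = 0) -> CTVolume:
    """Add i.i.d. zero-mean Gaussian noise (white; no streak or texture
    structure). ``sd_hu = 0`` returns an identical copy. Reproducible for a
    fixed seed."""
    if sd_hu < 0:
        raise ArgumentError("noise SD must be non-negative")
    out = volume.copy()
    if sd_hu == 0:
        return out
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out.values = out.values + rng.normal(0.0, sd_hu, size=out.shape).astype(out.values.dtype, copy=False)
    return out


def default_rois(spec: PhantomSpec) -> list:
    """Standard ROI set mirroring the study's placements: air anterior to
    the body wall, gluteal muscle, and the cortical wall of the left femoral
    shaft. Returned as :class:`uldct.metrics.ROISpec` objects (mm coords)."""
    from .metrics import ROISpec

    rois = [
        ROISpec(shape="box", center_mm=(0.0, -90.0, 0.0), size_mm=(30.0, 22.0, 45.0), label="air"),
        ROISpec(shape="sphere", center_mm=(60.0, 60.0, -20.0), size_mm=12.0, label="muscle"),
    ]
    if "left" in spec.sides and spec.include_shafts:
        cx, cy, cz = spec.sides["left"].head_center_mm
        zc = cz - spec.sides["left"].head_radius_mm - 2.0 - spec.shaft_length_mm / 2.0
        mid_wall = (spec.shaft_outer_radius_mm + spec.shaft_core_radius_mm) / 2.0
        rois.append(
            ROISpec(
                shape="box",
                center_mm=(cx + mid_wall, cy, zc),
                size_mm=(3.0, 3.0, 15.0),
                label="cortical_bone",
            )
        )
    return rois
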