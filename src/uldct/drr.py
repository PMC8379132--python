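"""Virtual radiographs by forward projection of CT volumes.

The projector computes, for every detector pixel, the line integral of the
linear attenuation coefficient along the ray from the X-ray source (cone
mode) or along a fixed direction (parallel mode). HU are converted to a
monoenergetic attenuation coefficient via

    mu(HU) = mu_water * (1 + HU / 1000),      clamped below at 0,

which is exact for the water/air calibration points of the Hounsfield scale.
Integrals are evaluated by midpoint quadrature with trilinear interpolation
of mu at uniformly spaced sample points along each ray (segment clipped to
the volume's bounding box); the default step is half the smallest voxel
dimension. Analytic slab/chord formulas — not a second code path — serve as
accuracy oracles in the test suite.

The cone geometry reproduces a supine anteroposterior pelvic radiograph: a
point source anterior to the patient, the center beam through a configurable
target point (clinically, the midpoint between the inter-ASIS line and the
superior pubic symphysis), a film-focus (source-detector) distance of 1.2 m
by default, and a detector plane orthogonal to the center beam. An object
in the detector-parallel plane through the target is magnified by
``sdd / sod``; angles between landmarks in that plane are preserved, which
is what makes radiographic angle measurement on these projections valid.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from .errors import ArgumentError, GeometryError
from .volume import CTVolume

__all__ = [
    "Detector",
    "ProjectionGeometry",
    "Radiograph",
    "hu_to_mu",
    "ray_integral",
    "project_cone",
    "project_parallel",
    "project_points",
    "to_display",
]

MU_WATER_PER_CM = 0.19  # monoenergetic default, configurable per call


@dataclass
class Detector:
    """Flat-panel detector: ``nu × nv`` square pixels of ``pitch_mm``.

    u runs along world +x and v along world +z for the default
    anteroposterior view; both lie in the detector plane.
    """

    nu: int = 430
    nv: int = 430
    pitch_mm: float = 1.0

    def validate(self) -> None:
        if self.nu < 1 or self.nv < 1:
            raise ArgumentError("detector must have at least one pixel per axis")
        if self.pitch_mm <= 0:
            raise ArgumentError("detector pitch must be positive")


@dataclass
class ProjectionGeometry:
    """Source/detector arrangement for one projection.

    ``sdd_mm`` is the film-focus (source-to-detector) distance and ``sod_mm``
    the source-to-target distance; the center beam runs along ``beam_dir``
    through ``target_mm`` and meets the detector center orthogonally.
    """

    mode: str = "cone"
    sdd_mm: float = 1200.0
    sod_mm: float = 1000.0
    target_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    beam_dir: tuple[float, float, float] = (0.0, 1.0, 0.0)
    u_dir: tuple[float, float, float] = (1.0, 0.0, 0.0)
    v_dir: tuple[float, float, float] = (0.0, 0.0, 1.0)
    detector: Detector = field(default_factory=Detector)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.mode not in ("cone", "parallel"):
            raise ArgumentError(f"unknown projection mode {self.mode!r}")
        b, u, v = (np.asarray(d, dtype=float) for d in (self.beam_dir, self.u_dir, self.v_dir))
        for name, d in (("beam_dir", b), ("u_dir", u), ("v_dir", v)):
            if np.linalg.norm(d) == 0:
                raise ArgumentError(f"{name} must be non-zero")
        b, u, v = b / np.linalg.norm(b), u / np.linalg.norm(u), v / np.linalg.norm(v)
        if max(abs(b @ u), abs(b @ v), abs(u @ v)) > 1e-9:
            raise GeometryError("beam, u and v directions must be mutually orthogonal")
        if self.mode == "cone" and not 0 < self.sod_mm < self.sdd_mm:
            raise GeometryError("cone mode requires 0 < sod < sdd")
        if self.sdd_mm <= 0:
            raise GeometryError("sdd must be positive")
        self.detector.validate()

    # -- derived geometry ---------------------------------------------------

    def _frame(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        b = np.asarray(self.beam_dir, dtype=float)
        u = np.asarray(self.u_dir, dtype=float)
        v = np.asarray(self.v_dir, dtype=float)
        return b / np.linalg.norm(b), u / np.linalg.norm(u), v / np.linalg.norm(v)

    @property
    def source_mm(self) -> np.ndarray:
        b, _, _ = self._frame()
        return np.asarray(self.target_mm, dtype=float) - self.sod_mm * b

    @property
    def detector_center_mm(self) -> np.ndarray:
        b, _, _ = self._frame()
        return np.asarray(self.target_mm, dtype=float) + (self.sdd_mm - self.sod_mm) * b

    def pixel_centers(self) -> np.ndarray:
        """World coordinates of all pixel centers, shape (nv, nu, 3)."""
        _, u, v = self._frame()
        det = self.detector
        du = (np.arange(det.nu) - (det.nu - 1) / 2.0) * det.pitch_mm
        dv = (np.arange(det.nv) - (det.nv - 1) / 2.0) * det.pitch_mm
        c = self.detector_center_mm
        return c[None, None, :] + du[None, :, None] * u[None, None, :] + dv[:, None, None] * v[None, None, :]

    def to_json(self, path) -> None:
        payload = {
            "mode": self.mode,
            "sdd_mm": self.sdd_mm,
            "sod_mm": self.sod_mm,
            "target_mm": list(self.target_mm),
            "beam_dir": list(self.beam_dir),
            "u_dir": list(self.u_dir),
            "v_dir": list(self.v_dir),
            "detector": {"nu": self.detector.nu, "nv": self.detector.nv, "pitch_mm": self.detector.pitch_mm},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)


@dataclass
class Radiograph:
    """A 2-D projection: ``raw`` line integrals (dimensionless, row = v,
    column = u) plus an optional display-mapped image."""

    raw: np.ndarray
    pitch_mm: float
    geometry: ProjectionGeometry
    display: np.ndarray | None = None


def hu_to_mu(volume: CTVolume, mu_water_per_cm: float = MU_WATER_PER_CM) -> np.ndarray:
    """Convert HU to linear attenuation in 1/mm (clamped at 0 below air)."""
    if mu_water_per_cm <= 0:
        raise ArgumentError("mu_water must be positive")
    mu_water_per_mm = mu_water_per_cm / 10.0
    mu = mu_water_per_mm * (1.0 + np.asarray(volume.values, dtype=np.float64) / 1000.0)
    return np.clip(mu, 0.0, None)


# ---------------------------------------------------------------------------
# ray integration core


def _clip_to_bounds(src: np.ndarray, dst: np.ndarray, lo: np.ndarray, hi: np.ndarray):
    """Slab-clip segments src->dst against the axis-aligned box [lo, hi].

    Returns (t_near, t_far) in segment parameter units, with t_near >= t_far
    marking rays that miss the box.
    """
    d = dst - src
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = (lo - src) / d
        t2 = (hi - src) / d
    t_lo = np.where(np.isnan(t1), -np.inf, np.minimum(t1, t2))
    t_hi = np.where(np.isnan(t1), np.inf, np.maximum(t1, t2))
    # axes with zero direction: inside the slab -> +-inf above; outside -> miss
    zero = d == 0
    outside = zero & ((src < lo) | (src > hi))
    t_near = np.clip(np.max(t_lo, axis=-1), 0.0, 1.0)
    t_far = np.clip(np.min(t_hi, axis=-1), 0.0, 1.0)
    t_far = np.where(np.any(outside, axis=-1), t_near, t_far)
    return t_near, t_far


def _integrate_segments(
    mu: np.ndarray,
    volume: CTVolume,
    src: np.ndarray,
    dst: np.ndarray,
    step_mm: float,
    max_samples_per_chunk: int = 4_000_000,
) -> np.ndarray:
    """Midpoint-rule integrals of mu along each src->dst segment (both
    (N, 3) arrays), trilinearly interpolated; outside the volume mu = 0."""
    lo, hi = volume.world_bounds()
    t_near, t_far = _clip_to_bounds(src, dst, lo, hi)
    seg = dst - src
    full_len = np.linalg.norm(seg, axis=-1)
    length = (t_far - t_near) * full_len
    out = np.zeros(src.shape[0])
    active = length > 0
    if not np.any(active):
        return out

    n_steps = max(1, int(math.ceil(float(length[active].max()) / step_mm)))
    chunk = max(1, max_samples_per_chunk // n_steps)
    spacing = np.asarray(volume.spacing_mm)
    origin = np.asarray(volume.origin_mm)
    idx_active = np.flatnonzero(active)
    for start in range(0, idx_active.size, chunk):
        sel = idx_active[start : start + chunk]
        tn = t_near[sel][:, None]
        tf = t_far[sel][:, None]
        frac = (np.arange(n_steps) + 0.5) / n_steps
        ts = tn + (tf - tn) * frac[None, :]
        pts = src[sel, None, :] + ts[:, :, None] * seg[sel, None, :]
        coords = (pts - origin) / spacing
        samples = map_coordinates(mu, coords.reshape(-1, 3).T, order=1, mode="constant", cval=0.0)
        samples = samples.reshape(len(sel), n_steps)
        out[sel] = samples.mean(axis=1) * length[sel]
    return out


def ray_integral(
    volume: CTVolume,
    src_mm,
    dst_mm,
    step_mm: float | None = None,
    mu: np.ndarray | None = None,
) -> float:
    """Path integral of attenuation along one segment (dimensionless).

    ``volume`` holds HU unless a precomputed attenuation grid ``mu`` (1/mm)
    is supplied. Converges to the analytic line integral as ``step_mm → 0``.
    """
    src = np.asarray(src_mm, dtype=float)
    dst = np.asarray(dst_mm, dtype=float)
    if np.allclose(src, dst):
        raise ArgumentError("zero-length ray")
    if step_mm is None:
        step_mm = min(volume.spacing_mm) / 2.0
    if step_mm <= 0:
        raise ArgumentError("step must be positive")
    if mu is None:
        mu = hu_to_mu(volume)
    return float(_integrate_segments(mu, volume, src[None, :], dst[None, :], step_mm)[0])


def _project(
    volume: CTVolume,
    geometry: ProjectionGeometry,
    step_mm: float | None,
    mu_water_per_cm: float,
    mu: np.ndarray | None,
) -> Radiograph:
    if step_mm is None:
        step_mm = min(volume.spacing_mm) / 2.0
    if step_mm <= 0:
        raise ArgumentError("step must be positive")
    if mu is None:
        mu = hu_to_mu(volume, mu_water_per_cm)
    det = geometry.detector
    pixels = geometry.pixel_centers().reshape(-1, 3)
    if geometry.mode == "cone":
        src = geometry.source_mm
        lo, hi = volume.world_bounds()
        if np.all(src >= lo) and np.all(src <= hi):
            raise GeometryError("X-ray source lies inside the volume")
        srcs = np.broadcast_to(src, pixels.shape).copy()
    else:
        b, _, _ = geometry._frame()
        srcs = pixels - geometry.sdd_mm * b
    raw = _integrate_segments(mu, volume, srcs, pixels, step_mm).reshape(det.nv, det.nu)
    return Radiograph(raw=raw, pitch_mm=det.pitch_mm, geometry=geometry)


def project_cone(
    volume: CTVolume,
    geometry: ProjectionGeometry | None = None,
    step_mm: float | None = None,
    mu_water_per_cm: float = MU_WATER_PER_CM,
    mu: np.ndarray | None = None,
) -> Radiograph:
    """Cone-beam projection: one ray from the point source through each
    detector-pixel center. The center beam passes through ``target_mm`` and
    hits the detector center."""
    if geometry is None:
        geometry = ProjectionGeometry(mode="cone")
    if geometry.mode != "cone":
        raise ArgumentError("geometry mode must be 'cone'")
    return _project(volume, geometry, step_mm, mu_water_per_cm, mu)


def project_parallel(
    volume: CTVolume,
    geometry: ProjectionGeometry | None = None,
    direction=None,
    detector: Detector | None = None,
    step_mm: float | None = None,
    mu_water_per_cm: float = MU_WATER_PER_CM,
    mu: np.ndarray | None = None,
) -> Radiograph:
    """Parallel-beam projection (magnification exactly 1), the idealized
    CT-stack geometry; used as the reference limit of the cone beam."""
    if geometry is None:
        kw = {}
        if direction is not None:
            d = np.asarray(direction, dtype=float)
            if np.linalg.norm(d) == 0:
                raise ArgumentError("direction must be non-zero")
            kw["beam_dir"] = tuple(d)
            if not np.allclose(d / np.linalg.norm(d), (0.0, 1.0, 0.0)):
                # build any orthonormal in-plane frame
                d = d / np.linalg.norm(d)
                helper = np.array([0.0, 0.0, 1.0]) if abs(d[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
                u = np.cross(helper, d)
                u /= np.linalg.norm(u)
                v = np.cross(d, u)
                kw["u_dir"], kw["v_dir"] = tuple(u), tuple(v)
        if detector is not None:
            kw["detector"] = detector
        geometry = ProjectionGeometry(mode="parallel", **kw)
    if geometry.mode != "parallel":
        raise ArgumentError("geometry mode must be 'parallel'")
    return _project(volume, geometry, step_mm, mu_water_per_cm, mu)


def project_points(geometry: ProjectionGeometry, points_mm) -> np.ndarray:
    """Map world points to detector (u, v) coordinates in mm.

    Cone mode intersects the source→point ray with the detector plane
    (central projection); parallel mode drops points along the beam. Used to
    carry phantom ground-truth landmarks onto a projection.
    """
    pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
    b, u, v = geometry._frame()
    c = geometry.detector_center_mm
    if geometry.mode == "cone":
        s = geometry.source_mm
        rel = pts - s
        depth = rel @ b
        if np.any(depth <= 0):
            raise GeometryError("point behind the source cannot be projected")
        scale = (geometry.sdd_mm / depth)[:, None]
        hit = s + rel * scale
    else:
        hit = pts + ((c - pts) @ b)[:, None] * b
    rel_det = hit - c
    return np.stack([rel_det @ u, rel_det @ v], axis=1)


def to_display(
    radiograph: Radiograph,
    window: tuple[float, float] | None = None,
    invert: bool = False,
) -> np.ndarray:
    """Linear window of raw integrals to 16-bit display.

    By default (no window) the raw min/max are used, so the full dynamic
    range is occupied; higher line integral (more bone) renders brighter
    unless ``invert``. The mapping is monotone and clipping is applied at
    the window edges.
    """
    raw = radiograph.raw
    if window is None:
        window = (float(raw.min()), float(raw.max()))
        if window[0] == window[1]:
            window = (window[0], window[0] + 1.0)
    wmin, wmax = window
    if not wmin < wmax:
        raise ArgumentError("window min must be below max")
    scaled = (raw - wmin) / (wmax - wmin)
    scaled = np.clip(scaled, 0.0, 1.0)
    if invert:
        scaled = 1.0 - scaled
    img = np.round(scaled * 65535.0).astype(np.uint16)
    radiograph.display = img
    return img
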