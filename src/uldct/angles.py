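"""Radiographic hip morphometry on 2-D images.

Two standard measures of acetabular coverage and inclination:

* lateral center-edge angle (Wiberg): angle between the image vertical
  through the femoral head center and the ray from the center to the
  lateral acetabular rim; positive when the rim lies lateral-superior.
* Sharp angle: angle between the inter-teardrop horizontal line and the
  line from the teardrop to the lateral acetabular rim.

The femoral head center may be recovered from contour points with an
algebraic (Kåsa) least-squares circle fit, which is exact for points on a
true circle. Coordinates are detector (u, v) in mm; image vertical defaults
to the detector v-axis. Both angles are invariant to uniform scaling of the
landmarks, which is why they transfer between cone-beam and parallel
projections of in-plane anatomy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ArgumentError

__all__ = ["AngleResult", "fit_circle", "ce_angle", "sharp_angle"]


@dataclass
class AngleResult:
    side: str
    method: str  # "ce" | "sharp"
    angle_deg: float
    head_center: tuple[float, float] | None = None
    head_radius: float | None = None

    @property
    def reported(self) -> float:
        """Angle rounded to the conventional 1 decimal."""
        return round(self.angle_deg, 1)


def fit_circle(points) -> tuple[tuple[float, float], float]:
    """Algebraic least-squares (Kåsa) circle fit to >= 3 points.

    Solves ``2·c·p + d = |p|²`` linearly for center c and offset d; exact on
    noiseless circles. Raises on collinear (degenerate) input.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] < 3 or pts.shape[1] != 2:
        raise ArgumentError("circle fit needs >= 3 2-D points")
    A = np.column_stack([2.0 * pts[:, 0], 2.0 * pts[:, 1], np.ones(len(pts))])
    b = (pts**2).sum(axis=1)
    sol, residuals, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 3:
        raise ArgumentError("collinear points: circle fit is degenerate")
    cx, cy, d = sol
    r2 = d + cx * cx + cy * cy
    if r2 <= 0:
        raise ArgumentError("degenerate circle fit (non-positive radius)")
    return (float(cx), float(cy)), float(math.sqrt(r2))


def _unit(vec, name: str) -> np.ndarray:
    v = np.asarray(vec, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ArgumentError(f"{name} must be non-zero")
    return v / n


def ce_angle(
    head_center,
    lateral_rim,
    vertical=(0.0, 1.0),
    lateral=None,
) -> float:
    """Lateral center-edge angle in degrees.

    ``vertical`` is the image direction toward superior; ``lateral`` the
    direction toward the lateral side of the measured hip (if omitted, the
    horizontal offset of the rim from the center defines it, so standard
    anatomy yields a positive angle). A rim directly superior gives 0°.
    """
    c = np.asarray(head_center, dtype=float)
    r = np.asarray(lateral_rim, dtype=float)
    d = r - c
    if np.allclose(d, 0):
        raise ArgumentError("rim coincides with head center")
    v = _unit(vertical, "vertical")
    if lateral is None:
        h = d - (d @ v) * v
        lat = h / np.linalg.norm(h) if np.linalg.norm(h) > 0 else np.array([v[1], -v[0]])
    else:
        lat = _unit(lateral, "lateral")
    return math.degrees(math.atan2(float(d @ lat), float(d @ v)))


def sharp_angle(teardrop, lateral_rim, horizontal=(1.0, 0.0)) -> float:
    """Sharp (acetabular inclination) angle in degrees, in [0, 90].

    Measured at the teardrop between the inter-teardrop horizontal line and
    the line to the lateral acetabular rim; a rim on the horizontal gives 0°.
    """
    t = np.asarray(teardrop, dtype=float)
    r = np.asarray(lateral_rim, dtype=float)
    d = r - t
    if np.allclose(d, 0):
        raise ArgumentError("rim coincides with teardrop")
    h = _unit(horizontal, "horizontal")
    along = abs(float(d @ h))
    perp = abs(float(d[0] * h[1] - d[1] * h[0]))
    return math.degrees(math.atan2(perp, along))
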