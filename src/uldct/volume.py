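"""In-memory CT volume container.

A :class:`CTVolume` is a 3-D grid of Hounsfield units on a regular,
axis-aligned lattice. World coordinates are millimetres on LPS-like axes:
axis 0 is +x (patient left), axis 1 is +y (posterior), axis 2 is +z
(superior). ``origin_mm`` is the world position of the *center* of voxel
(0, 0, 0); indices are 0-based and voxel centers are at
``origin + index * spacing``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ArgumentError


@dataclass
class CTVolume:
    """A 3-D scalar field in Hounsfield units with voxel geometry."""

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axes: str = field(default="LPS", repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)
        self.validate()

    def validate(self) -> None:
        if self.values.ndim != 3:
            raise ArgumentError("volume must be 3-D")
        if any(n < 2 for n in self.values.shape):
            raise ArgumentError(f"each axis needs >= 2 voxels, got {self.values.shape}")
        if any(s <= 0 for s in self.spacing_mm):
            raise ArgumentError(f"spacing must be positive, got {self.spacing_mm}")
        if not np.all(np.isfinite(self.values)):
            raise ArgumentError("HU values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def world_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Outer edges of the voxel lattice: (low corner, high corner) in mm."""
        sp = np.asarray(self.spacing_mm)
        org = np.asarray(self.origin_mm)
        lo = org - sp / 2.0
        hi = org + (np.asarray(self.shape) - 0.5) * sp
        return lo, hi

    def world_to_voxel(self, points_mm: np.ndarray) -> np.ndarray:
        """Map world mm coordinates to fractional voxel indices."""
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        return (pts - np.asarray(self.origin_mm)) / np.asarray(self.spacing_mm)

    def voxel_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        return np.asarray(self.origin_mm) + idx * np.asarray(self.spacing_mm)

    def contains_point(self, point_mm) -> bool:
        lo, hi = self.world_bounds()
        p = np.asarray(point_mm, dtype=float)
        return bool(np.all(p >= lo) and np.all(p <= hi))

    def coordinate_grids(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Sparse world-coordinate grids (x, y, z) broadcastable to shape."""
        axes = [
            self.origin_mm[a] + np.arange(self.shape[a]) * self.spacing_mm[a]
            for a in range(3)
        ]
        return np.meshgrid(*axes, indexing="ij", sparse=True)

    def copy(self) -> "CTVolume":
        return CTVolume(self.values.copy(), self.spacing_mm, self.origin_mm, self.axes)
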