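"""ROI-based quantitative image analysis.

Implements the study-style quality indices for cortical bone:

    noise = SD of HU in an air ROI outside the body
    SNR   = mean_cortical_bone / SD_air
    CNR   = (mean_cortical_bone − mean_muscle) / SD_cortical_bone
    FOM   = CNR² / effective_dose          (dose efficiency, per mSv)

Statistics use the sample SD (n−1 denominator). Indices are computed per
volume and only then summarized over a cohort — medians of inputs are never
fed into the ratio formulas, since medians do not commute with ratios.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .errors import ArgumentError, DivisionError, GeometryError
from .volume import CTVolume

__all__ = ["ROISpec", "ROIStats", "QualityIndices", "roi_stats", "noise", "quality_indices", "cohort_summary"]


@dataclass
class ROISpec:
    """A region of interest in world mm coordinates.

    ``shape`` is ``"sphere"`` (size = radius), ``"box"`` (size = half-extents
    per axis) or ``"circle"`` (a one-slice disc: size = (radius, slice z)).
    ``label`` tags the tissue the ROI is meant to sample.
    """

    shape: str
    center_mm: tuple[float, float, float]
    size_mm: float | tuple
    label: str = ""

    def mask(self, volume: CTVolume) -> np.ndarray:
        x, y, z = volume.coordinate_grids()
        cx, cy, cz = self.center_mm
        if self.shape == "sphere":
            r = float(self.size_mm)  # type: ignore[arg-type]
            m = (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= r * r
        elif self.shape == "box":
            hx, hy, hz = self.size_mm  # type: ignore[misc]
            m = (np.abs(x - cx) <= hx) & (np.abs(y - cy) <= hy) & (np.abs(z - cz) <= hz)
        elif self.shape == "circle":
            r, z0 = self.size_mm  # type: ignore[misc]
            m = ((x - cx) ** 2 + (y - cy) ** 2 <= r * r) & (np.abs(z - z0) <= volume.spacing_mm[2] / 2.0)
        else:
            raise ArgumentError(f"unknown ROI shape {self.shape!r}")
        return np.broadcast_to(m, volume.shape)

    @classmethod
    def from_dict(cls, d: dict) -> "ROISpec":
        size = d["size_mm"]
        return cls(
            shape=d["shape"],
            center_mm=tuple(d["center_mm"]),
            size_mm=tuple(size) if isinstance(size, (list, tuple)) else float(size),
            label=d.get("label", ""),
        )


def load_rois(path) -> list[ROISpec]:
    with open(path) as fh:
        return [ROISpec.from_dict(d) for d in json.load(fh)]


@dataclass
class ROIStats:
    mean_hu: float
    sd_hu: float
    n_voxels: int
    label: str = ""


@dataclass
class QualityIndices:
    snr: float
    cnr: float
    fom: float
    mean_bone_hu: float
    sd_bone_hu: float
    mean_muscle_hu: float
    sd_air_hu: float
    effective_dose_msv: float


def roi_stats(volume: CTVolume, roi: ROISpec) -> ROIStats:
    """Arithmetic mean and sample SD of HU over the ROI voxels."""
    mask = roi.mask(volume)
    # reject ROIs that poke outside the volume: compare against analytic extent
    lo, hi = volume.world_bounds()
    c = np.asarray(roi.center_mm)
    if roi.shape == "sphere":
        ext = np.full(3, float(roi.size_mm))  # type: ignore[arg-type]
    elif roi.shape == "box":
        ext = np.asarray(roi.size_mm, dtype=float)
    else:
        r, _ = roi.size_mm  # type: ignore[misc]
        ext = np.array([r, r, 0.0])
    if np.any(c - ext < lo) or np.any(c + ext > hi):
        raise GeometryError("ROI extends outside the volume")
    vals = volume.values[mask]
    n = int(vals.size)
    if n < 2:
        raise ArgumentError(f"ROI holds {n} voxels; need >= 2 for an SD")
    return ROIStats(
        mean_hu=float(vals.mean()),
        sd_hu=float(vals.std(ddof=1)),
        n_voxels=n,
        label=roi.label,
    )


def noise(volume: CTVolume, air_roi: ROISpec) -> float:
    """Image noise: SD of CT attenuation in an air ROI outside the body."""
    if air_roi.label != "air":
        raise ArgumentError("noise must be measured on an ROI labelled 'air'")
    return roi_stats(volume, air_roi).sd_hu


def quality_indices(
    mean_bone_hu: float,
    sd_bone_hu: float,
    mean_muscle_hu: float,
    sd_air_hu: float,
    effective_dose_msv: float,
) -> QualityIndices:
    """SNR, CNR and FOM from ROI statistics and the effective dose."""
    if sd_air_hu <= 0:
        raise DivisionError("SNR undefined: air SD must be positive")
    if sd_bone_hu <= 0:
        raise DivisionError("CNR undefined: cortical-bone SD must be positive")
    if effective_dose_msv <= 0:
        raise DivisionError("FOM undefined: effective dose must be positive")
    snr = mean_bone_hu / sd_air_hu
    cnr = (mean_bone_hu - mean_muscle_hu) / sd_bone_hu
    fom = cnr**2 / effective_dose_msv
    return QualityIndices(
        snr=float(snr),
        cnr=float(cnr),
        fom=float(fom),
        mean_bone_hu=float(mean_bone_hu),
        sd_bone_hu=float(sd_bone_hu),
        mean_muscle_hu=float(mean_muscle_hu),
        sd_air_hu=float(sd_air_hu),
        effective_dose_msv=float(effective_dose_msv),
    )


def cohort_summary(values, kind: str = "median") -> tuple[float, float, float]:
    """Summarize one metric over a cohort.

    ``kind="median"`` returns (median, Q1, Q3) with linear interpolation
    between order statistics; ``kind="mean"`` returns (mean, SD, n).
    """
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise ArgumentError("empty cohort")
    if kind == "median":
        if vals.size < 2:
            return float(vals[0]), float(vals[0]), float(vals[0])
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        return float(med), float(q1), float(q3)
    if kind == "mean":
        sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        return float(vals.mean()), sd, float(vals.size)
    raise ArgumentError(f"unknown summary kind {kind!r}")
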