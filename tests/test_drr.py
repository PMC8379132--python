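"""Forward projector: attenuation model, ray integrals, geometry laws."""

import numpy as np
import pytest

from conftest import HU_FOR_MU_002, sphere_volume
from uldct.drr import (
    Detector,
    ProjectionGeometry,
    Radiograph,
    hu_to_mu,
    project_cone,
    project_parallel,
    project_points,
    ray_integral,
    to_display,
)
from uldct.errors import ArgumentError, GeometryError
from uldct.volume import CTVolume


def shadow_width_mm(raw: np.ndarray, row: int, pitch: float) -> float:
    """Sphere-shadow diameter from the intensity-weighted second moment of a
    profile: for the semicircular chord profile of a homogeneous sphere,
    Var(u) = (D/4)^2, so D = 4*sqrt(Var). Robust to edge voxelization."""
    prof = raw[row]
    u = (np.arange(prof.size) - (prof.size - 1) / 2) * pitch
    w = prof / prof.sum()
    m = (u * w).sum()
    return 4.0 * np.sqrt(((u - m) ** 2 * w).sum())


class TestHuToMu:
    def test_water_air_and_linearity(self):
        vol = CTVolume(np.array([[[0.0, -1000.0], [1000.0, 500.0]]] * 2), (1, 1, 1))
        mu = hu_to_mu(vol, mu_water_per_cm=0.19)
        assert mu[0, 0, 0] == pytest.approx(0.019)
        assert mu[0, 0, 1] == 0.0
        assert mu[0, 1, 0] == pytest.approx(2 * 0.019)

    def test_clamped_below_zero(self):
        vol = CTVolume(np.full((2, 2, 2), -3000.0), (1, 1, 1))
        assert np.all(hu_to_mu(vol) == 0.0)


class TestRayIntegral:
    def test_homogeneous_slab(self):
        vals = np.full((50, 60, 50), -1000.0)
        vals[:, 20:40, :] = HU_FOR_MU_002  # 40 mm slab at 2 mm voxels
        vol = CTVolume(vals, (2, 2, 2), origin_mm=(-49, -59, -49))
        got = ray_integral(vol, (0, -200, 0), (0, 200, 0), step_mm=0.5)
        assert got == pytest.approx(0.8, rel=0.01)

    def test_sphere_center_chord(self, mu002_sphere30):
        got = ray_integral(mu002_sphere30, (0, -300, 0), (0, 300, 0), step_mm=0.25)
        assert got == pytest.approx(1.2, rel=0.01)

    def test_sphere_offset_chord(self, mu002_sphere30):
        """Chord at lateral offset d: length 2*sqrt(r^2-d^2)."""
        expected = 2 * np.sqrt(30**2 - 18**2) * 0.02
        got = ray_integral(mu002_sphere30, (18, -300, 0), (18, 300, 0), step_mm=0.25)
        assert got == pytest.approx(expected, rel=0.015)

    def test_step_halving_converges(self, mu002_sphere30):
        a = ray_integral(mu002_sphere30, (10, -300, 5), (10, 300, 5), step_mm=1.0)
        b = ray_integral(mu002_sphere30, (10, -300, 5), (10, 300, 5), step_mm=0.5)
        assert abs(a - b) / b < 0.005

    def test_zero_length_ray_rejected(self, mu002_sphere30):
        with pytest.raises(ArgumentError):
            ray_integral(mu002_sphere30, (1, 2, 3), (1, 2, 3))

    def test_ray_missing_volume_is_zero(self, mu002_sphere30):
        assert ray_integral(mu002_sphere30, (500, -300, 0), (500, 300, 0)) == 0.0


class TestConeProjection:
    def test_empty_volume_projects_to_zero(self):
        vol = CTVolume(np.full((20, 20, 20), -1000.0), (2, 2, 2), origin_mm=(-19, -19, -19))
        vr = project_cone(vol, ProjectionGeometry(detector=Detector(32, 32, 2.0)))
        assert np.all(vr.raw == 0.0)
        assert np.all(vr.raw >= 0.0)

    def test_shadow_magnified_by_sdd_over_sod(self, mu002_sphere25):
        geom = ProjectionGeometry(sdd_mm=1200, sod_mm=1000, detector=Detector(160, 160, 1.0))
        vr = project_cone(mu002_sphere25, geom, step_mm=1.0)
        assert shadow_width_mm(vr.raw, 80, 1.0) == pytest.approx(50 * 1200 / 1000, abs=1.0)

    @pytest.mark.parametrize("sod", [600.0, 900.0, 1100.0])
    def test_magnification_law_at_multiple_sods(self, mu002_sphere25, sod):
        geom = ProjectionGeometry(sdd_mm=1200, sod_mm=sod, detector=Detector(200, 200, 1.0))
        vr = project_cone(mu002_sphere25, geom, step_mm=1.0)
        assert shadow_width_mm(vr.raw, 100, 1.0) == pytest.approx(50 * 1200 / sod, abs=1.0)

    def test_source_inside_volume_rejected(self, mu002_sphere25):
        geom = ProjectionGeometry(sdd_mm=100, sod_mm=20, detector=Detector(16, 16, 4.0))
        with pytest.raises(GeometryError, match="source"):
            project_cone(mu002_sphere25, geom)

    def test_center_beam_hits_detector_center_through_target(self):
        geom = ProjectionGeometry(target_mm=(5.0, -3.0, 10.0))
        uv = project_points(geom, [(5.0, -3.0, 10.0)])
        assert uv[0] == pytest.approx((0.0, 0.0), abs=1e-9)


class TestParallelProjection:
    def test_unit_magnification(self, mu002_sphere25):
        vr = project_parallel(mu002_sphere25, detector=Detector(160, 160, 1.0), step_mm=1.0)
        assert shadow_width_mm(vr.raw, 80, 1.0) == pytest.approx(50.0, abs=1.0)

    def test_cone_approaches_parallel_at_large_sdd(self, mu002_sphere25):
        par = project_parallel(mu002_sphere25, detector=Detector(120, 120, 1.0), step_mm=1.0)
        far = ProjectionGeometry(mode="cone", sdd_mm=1e6, sod_mm=1e6 - 200, detector=Detector(120, 120, 1.0))
        cone = project_cone(mu002_sphere25, far, step_mm=1.0)
        assert np.max(np.abs(cone.raw - par.raw)) < 0.01 * par.raw.max()

    def test_total_signal_invariant_to_detector_shift(self):
        """Shifting the detector in-plane must not change the summed signal
        of a small object fully inside the field of view."""
        vol = sphere_volume(6.0, HU_FOR_MU_002, half_extent_mm=31.0, spacing=2.0)
        base = project_parallel(vol, detector=Detector(60, 60, 2.0), step_mm=1.0)
        shifted_geom = ProjectionGeometry(mode="parallel", target_mm=(8.0, 0.0, 6.0), detector=Detector(60, 60, 2.0))
        shifted = project_parallel(vol, shifted_geom, step_mm=1.0)
        assert shifted.raw.sum() == pytest.approx(base.raw.sum(), rel=1e-6)

    def test_zero_direction_rejected(self, mu002_sphere25):
        with pytest.raises(ArgumentError):
            project_parallel(mu002_sphere25, direction=(0, 0, 0))


def test_in_plane_angles_preserved_by_cone_projection(bilateral_phantom):
    """Landmarks in the detector-parallel plane through the target keep
    their angles under central magnification (basis of VR angle validity)."""
    from uldct.angles import ce_angle, fit_circle

    _, _, gt = bilateral_phantom
    cone = ProjectionGeometry(mode="cone", sdd_mm=1200, sod_mm=1000)
    contour = project_points(cone, gt.equator_points("left"))
    center, _ = fit_circle(contour)
    rim = project_points(cone, [gt.landmarks["left"]["rim"]])[0]
    measured = ce_angle(center, rim, lateral=(1.0, 0.0))
    assert measured == pytest.approx(gt.ce_angle_deg["left"], abs=0.5)


class TestDisplayMapping:
    def _flat(self, c):
        geom = ProjectionGeometry(detector=Detector(8, 8, 1.0))
        return Radiograph(raw=np.full((8, 8), c), pitch_mm=1.0, geometry=geom)

    def test_constant_maps_to_mid_gray(self):
        img = to_display(self._flat(3.0), window=(0.0, 6.0))
        assert abs(int(img[0, 0]) - 32768) <= 1

    def test_monotone(self):
        rng = np.random.default_rng(5)
        raw1 = rng.uniform(0, 2, (8, 8))
        raw2 = raw1 + rng.uniform(0, 1, (8, 8))
        geom = ProjectionGeometry(detector=Detector(8, 8, 1.0))
        d1 = to_display(Radiograph(raw1, 1.0, geom), window=(0.0, 3.0))
        d2 = to_display(Radiograph(raw2, 1.0, geom), window=(0.0, 3.0))
        assert np.all(d2.astype(int) >= d1.astype(int))

    def test_minmax_window_uses_full_range(self):
        rng = np.random.default_rng(6)
        raw = rng.uniform(1, 5, (8, 8))
        geom = ProjectionGeometry(detector=Detector(8, 8, 1.0))
        img = to_display(Radiograph(raw, 1.0, geom))  # default: min/max window
        assert img.min() == 0 and img.max() == 65535

    def test_degenerate_window_rejected(self):
        with pytest.raises(ArgumentError):
            to_display(self._flat(1.0), window=(2.0, 2.0))

    def test_invert_flips_polarity(self):
        rng = np.random.default_rng(7)
        raw = rng.uniform(0, 1, (8, 8))
        geom = ProjectionGeometry(detector=Detector(8, 8, 1.0))
        a = to_display(Radiograph(raw, 1.0, geom), window=(0.0, 1.0))
        b = to_display(Radiograph(raw, 1.0, geom), window=(0.0, 1.0), invert=True)
        assert np.all(a.astype(int) + b.astype(int) >= 65534)
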