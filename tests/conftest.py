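import numpy as np
import pytest

from uldct.volume import CTVolume

# HU value at which mu = 0.02/mm for the default mu_water of 0.19/cm
HU_FOR_MU_002 = (0.02 / 0.019 - 1.0) * 1000.0


def sphere_volume(radius_mm: float, hu_inside: float, half_extent_mm: float = 63.0,
                  spacing: float = 2.0) -> CTVolume:
    """Homogeneous sphere centered at the world origin in an air background."""
    n = int(round(2 * half_extent_mm / spacing)) + 1
    ax = -half_extent_mm + np.arange(n) * spacing
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij", sparse=True)
    vals = np.where(x**2 + y**2 + z**2 < radius_mm**2, hu_inside, -1000.0)
    return CTVolume(vals, (spacing,) * 3, origin_mm=(-half_extent_mm,) * 3)


@pytest.fixture(scope="session")
def mu002_sphere30():
    """Sphere of radius 30 mm with attenuation 0.02/mm."""
    return sphere_volume(30.0, HU_FOR_MU_002)


@pytest.fixture(scope="session")
def mu002_sphere25():
    """Sphere of radius 25 mm (diameter 50 mm) with attenuation 0.02/mm."""
    return sphere_volume(25.0, HU_FOR_MU_002)


@pytest.fixture(scope="session")
def bilateral_phantom():
    """Default bilateral pelvic phantom (noiseless) with ground truth."""
    from uldct.phantom import PhantomSpec, build_phantom

    spec = PhantomSpec.default_bilateral()
    volume, gt = build_phantom(spec)
    return spec, volume, gt
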