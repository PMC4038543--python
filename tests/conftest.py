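import numpy as np
import pytest

import glandnet as gn


@pytest.fixture(scope="session")
def small_phantom():
    """A 256 px phantom with 6 glands, shared across tests."""
    spec = gn.PhantomSpec(image_size_px=(256, 256), n_glands=6,
                          min_spacing_px=60, seed=1)
    img, truth = gn.generate_phantom(spec)
    return spec, img, truth


@pytest.fixture(scope="session")
def small_phantom_glands(small_phantom):
    _, img, _ = small_phantom
    return gn.segment_glands(img)


def ellipse_boundary(center, axes, theta_deg, n=200):
    """Analytic boundary points of a rotated ellipse in (x, y) coordinates."""
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    a, b = axes
    th = np.radians(theta_deg)
    x = a * np.cos(t)
    y = b * np.sin(t)
    xr = center[0] + x * np.cos(th) - y * np.sin(th)
    yr = center[1] + x * np.sin(th) + y * np.cos(th)
    return np.column_stack([xr, yr])


def angle_diff(a, b):
    """Smallest axial (mod 180) difference between two angles in degrees."""
    d = abs(a - b) % 180.0
    return min(d, 180.0 - d)
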