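import numpy as np
import pytest

from tomomorph.scene import Fibril, TomogramScene


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_sphere_volume(shape, centers, radii, voxel_size=1.0):
    """Label volume with one sphere per (center, radius), labels 1..n."""
    vol = np.zeros(shape, dtype=np.int32)
    ax = [np.arange(n) * voxel_size for n in shape]
    gx, gy, gz = np.meshgrid(*ax, indexing="ij")
    for lab, (c, r) in enumerate(zip(centers, radii), start=1):
        mask = (gx - c[0]) ** 2 + (gy - c[1]) ** 2 + (gz - c[2]) ** 2 <= r**2
        vol[mask] = lab
    return vol


@pytest.fixture
def two_sphere_scene():
    """Two spheres, radii 30 and 40 nm, centres 100 nm apart (1 nm voxels
    would be huge, so 2 nm voxels in a 220x120x120 nm box)."""
    vs = 2.0
    shape = (110, 60, 60)
    vol = make_sphere_volume(
        shape, centers=[(40.0, 60.0, 60.0), (140.0, 60.0, 60.0)],
        radii=[30.0, 40.0], voxel_size=vs,
    )
    return TomogramScene(label_volume=vol, voxel_size=vs, tomogram_id="two_spheres")


def straight_fibril(length=100.0, n=2, **kw):
    xs = np.linspace(0.0, length, n)
    pts = np.column_stack([xs, np.zeros(n), np.zeros(n)])
    return Fibril(points=pts, **kw)
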