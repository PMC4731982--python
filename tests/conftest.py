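import numpy as np
import pytest

from tlscanopy import (ReferenceConstellation, RigidTransform, ScanPointCloud,
                       SceneModel, ScannerSpec, SlabCanopy, SoilPlane)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_rotation(rng) -> np.ndarray:
    """Uniform random proper rotation via QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def random_rigid(rng, translation_scale: float = 10.0) -> RigidTransform:
    return RigidTransform(random_rotation(rng),
                          rng.uniform(-translation_scale, translation_scale, 3))


@pytest.fixture
def constellation(rng):
    """Five well-spread sphere centers at target-mount height."""
    centers = rng.uniform(0.0, 12.0, size=(5, 3))
    centers[:, 2] = rng.uniform(1.3, 1.7, size=5)
    return ReferenceConstellation({f"S{i}": c for i, c in enumerate(centers)})


@pytest.fixture
def flat_slab_scene():
    """Gently tilted soil with a 1 m uniform canopy slab and 4 spheres."""
    return SceneModel(
        soil=SoilPlane(a=0.05, b=0.01),
        canopies=[SlabCanopy((0.5, 3.5, 0.5, 3.5), height=1.0)],
        sphere_centers={"S1": (0.2, 0.2, 1.5), "S2": (3.8, 0.2, 1.5),
                        "S3": (0.2, 3.8, 1.5), "S4": (3.8, 3.8, 1.6)},
    )


@pytest.fixture
def coarse_scanner():
    """A coarse angular grid (fast tests): ~8 mm ground spacing at 4 m range."""
    return ScannerSpec(position=(-1.0, -1.0, 3.5), resolution_fraction=1.0,
                       base_angular_step=2e-3, range_noise_sd=0.0)


def synthetic_canopy_cloud(rng, n: int = 10_000, height: float = 1.0,
                           spread: float = 0.05,
                           extent: tuple = (0.0, 4.0, 0.0, 4.0)) -> ScanPointCloud:
    """Height-above-soil cloud: canopy returns near `height` (truncated below
    it is a one-sided canopy-top population)."""
    x0, x1, y0, y1 = extent
    xy = rng.uniform([x0, y0], [x1, y1], size=(n, 2))
    z = height - np.abs(rng.normal(0.0, spread, size=n))
    return ScanPointCloud(np.column_stack([xy, z]), scan_id="canopy", frame="fixed")
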