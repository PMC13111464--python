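import numpy as np
import pytest

from phenopoint import PlantSpec, PointCloud, generate_plant


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cloud(rng):
    """Unlabeled 50-point cloud with random colors."""
    coords = rng.uniform(-100, 100, (50, 3))
    colors = rng.integers(0, 256, (50, 3))
    return PointCloud(coords, colors)


@pytest.fixture
def labeled_cloud(rng):
    coords = rng.uniform(0, 200, (80, 3))
    colors = rng.integers(0, 256, (80, 3))
    labels = rng.integers(0, 5, 80)
    return PointCloud(coords, colors, labels)


@pytest.fixture(scope="session")
def synthetic_plant():
    """One deterministic plant with ground truth, shared across tests."""
    return generate_plant(PlantSpec(seed=7, flying_pixel_count=400))
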