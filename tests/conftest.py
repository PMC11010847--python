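import numpy as np
import pytest
from scipy.spatial import cKDTree

from pigback import PointCloud
from pigback.synth import PigSpec, make_pig, make_scene, sample_spec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_spec():
    return PigSpec(seed=42, yaw_deg=8.0)


@pytest.fixture(scope="session")
def default_pig():
    return make_pig(PigSpec(seed=42, yaw_deg=8.0))


@pytest.fixture(scope="session")
def default_scene():
    return make_scene(PigSpec(seed=42, yaw_deg=8.0))


def transfer_labels(sample, cloud):
    """Label each point of ``cloud`` by its nearest neighbor in the sample."""
    tree = cKDTree(sample.cloud.points)
    _, nn = tree.query(cloud.points)
    return sample.labels[nn]


def random_colored_cloud(rng, n=100):
    pts = rng.uniform(-2, 2, size=(n, 3))
    colors = rng.integers(0, 256, size=(n, 3))
    return PointCloud(pts, colors, source_id="random")
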