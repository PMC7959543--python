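import numpy as np
import pytest

from frontfish import SceneConfig, make_leader_scene


@pytest.fixture(scope="session")
def default_scene():
    """One seeded leader-cell scene shared by read-only tests."""
    return make_leader_scene(SceneConfig(seed=42))


@pytest.fixture
def parallel_edges():
    """Two straight vertical edges 10 µm apart: invasive at x=0, nuclear at x=10."""
    from frontfish import EdgeAnnotation

    return EdgeAnnotation(
        invasive_edge=[[0.0, 0.0], [0.0, 20.0]],
        nuclear_edge=[[10.0, 0.0], [10.0, 20.0]],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
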