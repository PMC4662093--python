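import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from geocov.synthetic import SceneSpec, generate_scene


@pytest.fixture(scope="session")
def scene():
    """Default synthetic scene (seed 1): grid roads, uniform census,
    half-plane landcover, flat DEM, constant vegetation stacks."""
    return generate_scene(SceneSpec(seed=1))


@pytest.fixture(scope="session")
def node_site(scene):
    """The site placed exactly on a road-grid node and the landcover split."""
    return scene.sites[0]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
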