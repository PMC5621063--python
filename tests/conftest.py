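import numpy as np
import pytest

from patchscale import RasterBand, SceneSpec, generate_scene_pair


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def checker_band():
    """8x8 band with deterministic non-trivial structure."""
    vals = 0.2 + 0.05 * np.indices((8, 8)).sum(axis=0) % 3 * 0.1
    return RasterBand(vals, None, 30.0, "red")


@pytest.fixture(scope="session")
def small_scene_pair():
    """One 64x64 synthetic scene triple at s=2, shared across tests."""
    return generate_scene_pair(SceneSpec(hr_shape=(64, 64), s=2, seed=7))
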