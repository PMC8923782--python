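import numpy as np
import pytest
from hypothesis import settings

from spurnet import SceneSpec, generate_scene

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from spurnet.preprocess import normalize


@pytest.fixture(scope="session")
def small_scene():
    """One deterministic 64×64 tongue scene (raw image + exact mask)."""
    return generate_scene(SceneSpec(side=64, seed=7))


@pytest.fixture(scope="session")
def canonical_scene():
    """One deterministic 256×256 tongue scene."""
    return generate_scene(SceneSpec(seed=7))


@pytest.fixture(scope="session")
def normalized_small_scene(small_scene):
    img, mask = small_scene
    return normalize(img), mask


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
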