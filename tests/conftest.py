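import numpy as np
import pytest

from plantarseg import BinaryMask, SceneConfig, generate_scene


def make_mask(arr) -> BinaryMask:
    return BinaryMask(data=np.asarray(arr, dtype=np.uint8))


def random_mask(rng, shape=(64, 64), p=0.5) -> BinaryMask:
    return BinaryMask(data=(rng.random(shape) < p).astype(np.uint8))


@pytest.fixture(scope="session")
def default_scene():
    """One default synthetic scene (frame + exact ground truth), seed 1."""
    return generate_scene(SceneConfig(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
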