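import numpy as np
import pytest

from petgeom import PETVolume


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_volume(seed: int, shape=(20, 20, 20), spacing=(3.0, 3.0, 3.0)) -> PETVolume:
    gen = np.random.default_rng(seed)
    return PETVolume(gen.uniform(0.0, 10.0, size=shape), spacing)


def random_blob_mask(seed: int, shape=(20, 20, 20)) -> np.ndarray:
    """A random connected blob: union of a few overlapping digitized balls."""
    gen = np.random.default_rng(seed)
    grid = np.stack(np.meshgrid(*[np.arange(n) for n in shape], indexing="ij"), axis=-1)
    center = np.array(shape) / 2.0
    mask = np.zeros(shape, dtype=bool)
    point = center
    for _ in range(gen.integers(1, 5)):
        radius = gen.uniform(2.0, 5.0)
        mask |= np.linalg.norm(grid - point, axis=-1) <= radius
        point = point + gen.uniform(-3.0, 3.0, size=3)
        point = np.clip(point, 2, np.array(shape) - 3)
    return mask


@pytest.fixture
def blob_mask():
    return random_blob_mask(7)
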