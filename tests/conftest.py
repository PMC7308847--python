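import numpy as np
import pytest

import rankflat as rf


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture(scope="session")
def small_collection():
    """A 32x32 RGB collection of 12 tiles with every pathology enabled."""
    cfg = rf.SynthConfig(height=32, width=32, n_tiles=12, seed=7)
    observed, content, truth = rf.make_collection(cfg)
    return cfg, observed, content, truth


@pytest.fixture
def gradient_stack(rng):
    """A gray stack of 6 smooth gradient tiles with mild noise, 16x16."""
    y, x = np.mgrid[0:16, 0:16]
    base = 100.0 + 3.0 * y + 2.0 * x
    tiles = base[None] * (1.0 + rng.normal(0, 0.01, size=(6, 16, 16)))
    return rf.TileStack(tiles[..., None], bit_depth_max=255.0)
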