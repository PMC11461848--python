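import numpy as np
import pytest

from volfuse.synthetic import PhantomConfig, gen_planted_selection, gen_volumes


@pytest.fixture(scope="session")
def small_phantoms():
    """12 easy 16^3 phantoms, 3 balanced classes."""
    cfg = PhantomConfig(n_samples=12, n_classes=3, shape=(16, 16, 16),
                        noise_sd=0.02, jitter_voxels=1, seed=7)
    return gen_volumes(cfg)


@pytest.fixture(scope="session")
def planted_problem():
    return gen_planted_selection(n=150, N=30, k_informative=5,
                                 effect_size=2.0, seed=3)


@pytest.fixture(scope="session")
def separable_features():
    """Trivially separable 3-class feature matrix."""
    rng = np.random.default_rng(0)
    y = np.repeat([0, 1, 2], 20)
    x = rng.standard_normal((60, 5)) * 0.05
    x[:, 0] += y * 5.0
    return x, y
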