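import numpy as np
import pytest

from lamt2 import phantom


DESK_GRID = (8, 64, 64)


@pytest.fixture(scope="session")
def noiseless_phantom():
    spec = phantom.PhantomSpec(grid_shape=DESK_GRID, noise_sigma=0.0, seed=11)
    return phantom.generate_phantom(spec)


@pytest.fixture(scope="session")
def noisy_phantom():
    spec = phantom.PhantomSpec(grid_shape=DESK_GRID, noise_sigma=3.0, seed=12)
    return phantom.generate_phantom(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_blob_mask(rng, shape=(4, 12, 12), n_seeds=3, grow=10):
    """Random connected-ish binary mask built by dilating seed voxels."""
    from scipy import ndimage

    m = np.zeros(shape, dtype=bool)
    idx = tuple(rng.integers(0, s, n_seeds) for s in shape)
    m[idx] = True
    for _ in range(grow):
        cand = ndimage.binary_dilation(m) & ~m
        coords = np.argwhere(cand)
        if len(coords) == 0:
            break
        take = coords[rng.random(len(coords)) < 0.6]
        m[tuple(take.T)] = True
    return m
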