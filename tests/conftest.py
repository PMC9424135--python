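import numpy as np
import pytest

from clauseg.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_phantom():
    """One deterministic 48-cube phantom (volume, mask, scan age)."""
    spec = PhantomSpec(grid=(48, 48, 48), seed=7)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def noise_free_phantom():
    spec = PhantomSpec(grid=(48, 48, 48), seed=7, noise_sigma=0.0, bias_amplitude=0.0)
    return generate_phantom(spec)


def random_blob_mask(rng, shape, n_seeds=3):
    """Small random nonempty mask: a few dilated seed points."""
    from scipy import ndimage
    mask = np.zeros(shape, dtype=bool)
    idx = tuple(rng.integers(0, s, size=n_seeds) for s in shape)
    mask[idx] = True
    mask = ndimage.binary_dilation(mask, iterations=int(rng.integers(1, 3)))
    return mask
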