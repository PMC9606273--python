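import numpy as np
import pytest

import remodel as rm


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free, default-geometry phantom pair of image and truth masks."""
    params = rm.PhantomParams(noise_sd=0)
    image, masks = rm.make_phantom(params)
    return params, image, masks


@pytest.fixture(scope="session")
def noisy_phantom():
    params = rm.PhantomParams()
    image, masks = rm.make_phantom(params)
    return params, image, masks


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
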