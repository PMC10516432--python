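import numpy as np
import pytest

import v1sparse as v


@pytest.fixture(scope="session")
def pink_images():
    """Six preprocessed 128x128 pink-noise images shared across tests."""
    raw = v.generate_pink_noise_images(v.PinkNoiseSpec(128, 128, 1.0, seed=42), 6)
    return [v.preprocess_image(im) for im in raw]


@pytest.fixture(scope="session")
def small_bank():
    """Grating bank for 16x16 patches (session-scoped: construction is the slow part)."""
    return v.make_grating_bank(16)


@pytest.fixture(scope="session")
def tiny_dictionary():
    """Incoherent-ish 8x20 unit-norm dictionary for coding tests."""
    return v.random_unit_dictionary(8, 20, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
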