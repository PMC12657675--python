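import numpy as np
import pytest

from adgrade import synthetic_mri as smri


@pytest.fixture(scope="session")
def small_dataset():
    """4 x 30 phantoms at 32x32 with default noise (session-cached)."""
    return smri.generate_dataset((30, 30, 30, 30), image_size=32, seed=101)


@pytest.fixture(scope="session")
def medium_dataset():
    """4 x 100 phantoms at 32x32 (session-cached; used by training tests)."""
    return smri.generate_dataset((100, 100, 100, 100), image_size=32, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
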