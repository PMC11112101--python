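import numpy as np
import pytest

from csfpulse import PhantomSpec, make_phantom, region_spectra


@pytest.fixture(scope="session")
def small_phantom():
    """One small default-physics phantom shared across tests (seeded)."""
    spec = PhantomSpec(shape=(32, 32, 12, 600), seed=42)
    image, labels, truth = make_phantom(spec)
    return image, labels, truth


@pytest.fixture(scope="session")
def small_phantom_spectra(small_phantom):
    image, labels, _ = small_phantom
    return region_spectra(image, labels)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
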