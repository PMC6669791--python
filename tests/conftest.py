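import numpy as np
import pytest

from bibnet.core_io import ImageGrid
from bibnet.phantoms import PhantomSpec, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_grid(rng):
    """A seeded 12x10x8 intensity grid with anisotropic spacing."""
    values = rng.normal(0.0, 200.0, size=(12, 10, 8)).astype(np.float32)
    return ImageGrid(values, spacing=(1.17, 1.17, 3.0), origin=(-5.0, 2.0, 10.0))


@pytest.fixture(scope="session")
def phantom_pair():
    """One noise-free phantom with its structures (plus body mask)."""
    spec = PhantomSpec(noise_sd=0.0, seed=5)
    return generate_phantom(spec, include_body=True)


@pytest.fixture(scope="session")
def noisy_phantom():
    spec = PhantomSpec(seed=11)
    return generate_phantom(spec)
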