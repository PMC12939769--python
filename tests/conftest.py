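import numpy as np
import pytest

from blastoseg.phantom import PhantomParams, generate_dataset, generate_phantom


@pytest.fixture(scope="session")
def small_phantoms():
    """A handful of 64x64 phantoms shared across cheap tests."""
    return generate_dataset(6, size=64, seed=123)


@pytest.fixture(scope="session")
def one_phantom():
    return generate_phantom(PhantomParams.for_size(96, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
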