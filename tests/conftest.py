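import numpy as np
import pytest

from ivusseg import PhantomSpec, generate


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_phantom():
    """One speckled phantom with defaults, shared across tests."""
    return generate(PhantomSpec(seed=7))


@pytest.fixture(scope="session")
def clean_phantom():
    """Speckle-free phantom: piecewise-constant layers plus artifacts."""
    return generate(PhantomSpec(seed=7, speckle_scale=0.0))
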