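import numpy as np
import pytest

from valvequant.phantoms import MPMPhantomSpec, generate_mpm_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_mpm_phantom():
    """One deterministic small SHG/CARS phantom pair shared across tests."""
    spec = MPMPhantomSpec(size_px=(128, 128), n_slices=2, fiber_density=0.10,
                          seed=7)
    return generate_mpm_phantom(spec)
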