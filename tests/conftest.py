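import numpy as np
import pytest

from minipae.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def emphysema_phantom():
    """One phantom with three low-attenuation lesions, plus its truth."""
    spec = PhantomSpec(lesion_count=3, seed=5)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def normal_phantom():
    spec = PhantomSpec(seed=6)
    return generate_phantom(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
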