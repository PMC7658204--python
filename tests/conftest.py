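import numpy as np
import pytest

from ctmorphseg import PhantomSpec, render_phantom


@pytest.fixture(scope="session")
def phantom():
    """One default phantom shared by read-only tests."""
    return render_phantom(PhantomSpec(seed=7))


@pytest.fixture(scope="session")
def quiet_phantom():
    """Noise-free phantom for exact HU/label consistency checks."""
    return render_phantom(PhantomSpec(seed=7, noise_sigma_hu=0.0))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
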