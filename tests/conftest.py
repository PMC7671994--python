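import numpy as np
import pytest

from iusreg import PhantomSpec, make_pair
from iusreg.experiments import phantom_spec_for_shape


@pytest.fixture(scope="session")
def small_pair():
    """48^3 cavity-bearing phantom pair, session-cached."""
    return make_pair(phantom_spec_for_shape((48, 48, 48), 0.5, seed=7,
                                            cavity_radius=4.0,
                                            max_displacement=3.0))


@pytest.fixture(scope="session")
def flat_pair():
    """Cavity-free, deformation-free pair (speckle differences only)."""
    return make_pair(phantom_spec_for_shape((32, 32, 32), 1.0, seed=3,
                                            cavity_radius=0.0,
                                            max_displacement=0.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
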