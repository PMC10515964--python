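import numpy as np
import pytest

from devatlas.synthetic import PhantomSpec, make_phantom


@pytest.fixture(scope="session")
def phantom48():
    """Blob phantom with an asymmetric structure layout, 48^3, no noise."""
    return make_phantom(PhantomSpec(shape=(48, 48, 48), n_random=8,
                                    asymmetry=0.12, seed=3))


@pytest.fixture(scope="session")
def phantom_small():
    return make_phantom(PhantomSpec(shape=(24, 24, 24), n_random=5, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
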