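import numpy as np
import pytest

from leatherback_pva import StochasticSpec, load_table1


@pytest.fixture(scope="session")
def base():
    return load_table1()


@pytest.fixture(scope="session")
def small_spec():
    """Cheap Monte-Carlo design for unit tests."""
    return StochasticSpec(n_trajectories=50, horizon=40, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
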