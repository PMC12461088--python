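import numpy as np
import pytest

from regconn.simulate import generate_network, simulate_session


@pytest.fixture(scope="session")
def default_net():
    """One network at the default generation parameters."""
    return generate_network(rng_seed=1234)


@pytest.fixture(scope="session")
def default_session(default_net):
    """One 250-timepoint session at noise 0.5 from the default network."""
    return simulate_session(default_net, 250, 0.5, rng_seed=77)


@pytest.fixture(scope="session")
def small_net():
    """A 20-node single-module network for fast estimator tests."""
    return generate_network(
        p=20, n_modules=1, module_size=20, growth_edges=4,
        extra_modular_target=0, rng_seed=9,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
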