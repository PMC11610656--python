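import numpy as np
import pytest

from kelpres import baseline_parameters


@pytest.fixture(scope="session")
def baseline():
    return baseline_parameters()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def baseline_equilibria(baseline):
    """Labeled equilibria at the baseline parameters (computed once)."""
    from kelpres.equilibria import find_equilibria

    return find_equilibria(baseline)


def random_states(rng, n, scale=(12000.0, 60.0, 8.0)):
    """Nonnegative reduced states spanning the biologically relevant box."""
    return rng.uniform(0.0, 1.0, size=(n, 3)) * np.asarray(scale)
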