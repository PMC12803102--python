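import numpy as np
import pytest

import coherosc as co


@pytest.fixture(scope="session")
def trimolecular():
    return co.fixture("trimolecular")


@pytest.fixture(scope="session")
def brusselator():
    return co.fixture("brusselator")


@pytest.fixture(scope="session")
def two_state_generator():
    fx = co.fixture("two-state")
    space = co.enumerate_states(fx.network, "closed-conserved", total=1)
    return co.build_generator(fx.network, space)


@pytest.fixture(scope="session")
def trimolecular_generator(trimolecular):
    """Generator on the conserved total-20 shell (231 states)."""
    space = co.enumerate_states(trimolecular.network, "closed-conserved",
                                total=20)
    return co.build_generator(trimolecular.network, space)


@pytest.fixture(scope="session")
def trimolecular_generator_small(trimolecular):
    space = co.enumerate_states(trimolecular.network, "closed-conserved",
                                total=8)
    return co.build_generator(trimolecular.network, space)


def random_generator_matrix(rng, n):
    """A random proper generator: uniform off-diagonal rates."""
    m = rng.uniform(0.0, 1.0, (n, n))
    np.fill_diagonal(m, 0.0)
    np.fill_diagonal(m, -m.sum(axis=0))
    return m
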