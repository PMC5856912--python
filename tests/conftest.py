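from fractions import Fraction as F

import pytest

import crndist as cd


@pytest.fixture(scope="session")
def examples():
    """Named worked-example fixtures (pmfs, formula, holder networks)."""
    return cd.fixtures.worked_examples()


@pytest.fixture(scope="session")
def pi1():
    return cd.Pmf({3: F(1, 6), 0: F(5, 6)})


@pytest.fixture(scope="session")
def pi2():
    return cd.Pmf({5: F(1, 2), 1: F(1, 2)})


@pytest.fixture(scope="session")
def three_point():
    return cd.Pmf({2: F(1, 6), 5: F(1, 3), 10: F(1, 2)})


@pytest.fixture(scope="session")
def joint_2d():
    return cd.Pmf({(3, 1): F(1, 6), (3, 2): F(1, 3), (1, 5): F(1, 2)})


def output_pmf(system, max_states=100_000):
    """Exact absorption marginal of a network's declared outputs."""
    return cd.output_distribution(system, max_states=max_states)
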