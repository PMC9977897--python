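import numpy as np
import pytest

from latentcorr import CumulativeProbMatrix, from_pmf, make_marginal


@pytest.fixture(scope="session")
def uniform01():
    return make_marginal("uniform", (0, 1))


@pytest.fixture(scope="session")
def std_normal():
    return make_marginal("normal")


@pytest.fixture(scope="session")
def std_laplace():
    return make_marginal("laplace")


@pytest.fixture
def indep_2x2():
    return from_pmf([[0.25, 0.25], [0.25, 0.25]])


def random_table(rng: np.random.Generator, I: int, J: int) -> CumulativeProbMatrix:
    """Random valid cumulative probability matrix via a Dirichlet cell draw."""
    pmf = rng.dirichlet(np.ones(I * J)).reshape(I, J)
    return from_pmf(pmf)
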