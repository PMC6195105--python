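import numpy as np
import pytest

from biasedbayes.inference import (
    DiscreteDistribution,
    GaussianDist,
    LikelihoodTable,
)


@pytest.fixture
def disease():
    """Rare-disease screening problem: prior 1/10,000, 99% test accuracy."""
    support = np.array(["ill", "healthy"])
    prior = DiscreteDistribution.from_probs(support, [0.0001, 0.9999])
    likelihood = LikelihoodTable.from_weights(support, [0.99, 0.01])
    return prior, likelihood


@pytest.fixture
def gaussian_pair():
    """Prior N(0,1), likelihood N(3,1) — the conjugate workhorse."""
    return GaussianDist(0.0, 1.0), GaussianDist(3.0, 1.0)


@pytest.fixture
def wide_grid():
    """Grid wide enough that every biased Gaussian posterior in the test
    lattice keeps negligible tail mass outside it."""
    return np.linspace(-12.0, 15.0, 4001)


def random_discrete_problem(rng, n=None, support=None):
    """A random prior/likelihood pair on a shared numeric support."""
    if support is not None:
        n = len(support)
    else:
        if n is None:
            n = int(rng.integers(2, 12))
        support = np.sort(rng.normal(0, 3, n) + np.arange(n) * 1e-6)
    prior = DiscreteDistribution.from_probs(support, rng.dirichlet(np.ones(n)))
    likelihood = LikelihoodTable.from_weights(support, rng.uniform(0.01, 1.0, n))
    return prior, likelihood
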