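import warnings

import numpy as np
import pytest

from wcep import (
    ComponentSet,
    illness_death_tree,
    two_transient_tree,
)


@pytest.fixture(scope="session")
def nf_components():
    return ComponentSet(("N", "F"), (False, True))


@pytest.fixture(scope="session")
def nmf_components():
    return ComponentSet(("N", "M", "F"), (False, False, True))


@pytest.fixture(scope="session")
def illness_tree():
    return illness_death_tree()


@pytest.fixture(scope="session")
def five_type_tree():
    return two_transient_tree()


@pytest.fixture(scope="session")
def exhaustive_scheme(illness_tree, nf_components):
    return illness_tree.scheme(nf_components, "exhaustive")


@pytest.fixture(scope="session")
def marginal_scheme(illness_tree, nf_components):
    return illness_tree.scheme(nf_components, "marginal")


@pytest.fixture(autouse=True)
def _silence_extrapolation_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        yield


def random_pd(rng, K, scale=1.0):
    """Random well-conditioned positive-definite covariance matrix."""
    A = rng.normal(size=(K, K))
    V = A @ A.T + K * np.eye(K)
    return scale * V
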