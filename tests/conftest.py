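import numpy as np
import pytest

from nirspace import (
    SessionParams,
    build_feature_matrix,
    preprocess_session,
    simulate_session,
)


@pytest.fixture(scope="session")
def default_session():
    """One full default session (60 trials): (od, events)."""
    return simulate_session(SessionParams(seed=11))


@pytest.fixture(scope="session")
def default_epochs(default_session):
    od, events = default_session
    return preprocess_session(od, events)


@pytest.fixture(scope="session")
def avg_type4_features(default_epochs):
    """The D = 480 single-feature matrix of the default session."""
    return build_feature_matrix(default_epochs, features=("AVG",), scheme=4)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def gaussian_features(n_per_class=20, n_features=8, separation=0.0, seed=0,
                      informative="all"):
    """Two-class Gaussian feature matrix for classifier-level tests.

    ``informative="all"`` shifts every feature by ``separation`` for one
    class (well-separated clouds); ``"first"`` shifts only column 0.
    """
    from nirspace.features import FeatureDescriptor, FeatureMatrix

    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    values = rng.standard_normal((n, n_features))
    labels = np.array(
        ["mental_arithmetic", "idle"] * n_per_class, dtype=object
    )
    cols = slice(None) if informative == "all" else 0
    values[labels == "mental_arithmetic", cols] += separation
    columns = [
        FeatureDescriptor("AVG", "HbO", f"F{j}", (0.0, float(j + 1)))
        for j in range(n_features)
    ]
    return FeatureMatrix(values=values, columns=columns, labels=labels)
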