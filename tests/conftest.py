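import numpy as np
import pytest

from vjump import ObservationScheme, VelocityJumpModel, validate_model


@pytest.fixture
def two_state():
    """Symmetric forward/backward switcher."""
    return validate_model(
        VelocityJumpModel([1.0, -1.0], [1.0, 1.0], [[0, 1], [1, 0]])
    )


@pytest.fixture
def two_state_uneven():
    return validate_model(
        VelocityJumpModel([1.0, -1.0], [1.0, 2.0], [[0, 1], [1, 0]])
    )


@pytest.fixture
def three_state():
    """Forward / stationary / backward with unequal rates."""
    return validate_model(
        VelocityJumpModel(
            [1.0, 0.0, -1.0],
            [1.0, 2.0, 0.5],
            [[0, 0.5, 0.5], [0.5, 0, 0.5], [0.5, 0.5, 0]],
        )
    )


@pytest.fixture
def scheme():
    return ObservationScheme(dt=1.0, sigma=0.05)


def random_model(rng, n=None):
    """A random valid (irreducible) model with n in 2..6."""
    n = n or rng.integers(2, 7)
    P = rng.random((n, n))
    np.fill_diagonal(P, 0.0)
    # guarantee irreducibility with a cycle
    for s in range(n):
        P[s, (s + 1) % n] += 0.5
    P /= P.sum(axis=1, keepdims=True)
    return validate_model(
        VelocityJumpModel(
            rng.normal(0, 1, n), rng.uniform(0.1, 3.0, n), P
        )
    )
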