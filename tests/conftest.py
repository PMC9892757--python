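import numpy as np
import pytest

from mdagcan import AssociationMatrix, RunConfig, SyntheticSpec, generate_associations


@pytest.fixture
def identity_assoc():
    """2x2 identity association matrix (the smallest non-trivial case)."""
    return AssociationMatrix(
        np.eye(2), ("d1", "d2"), ("m1", "m2")
    )


@pytest.fixture
def toy_assoc():
    """3 diseases x 4 microbes with a few associations."""
    values = np.array([
        [1.0, 0.0, 1.0, 0.0],
        [0.0, 1.0, 0.0, 0.0],
        [1.0, 0.0, 0.0, 1.0],
    ])
    return AssociationMatrix(
        values, ("d1", "d2", "d3"), ("m1", "m2", "m3", "m4")
    )


@pytest.fixture
def small_synthetic():
    """Small planted-structure matrix for training smoke tests."""
    A, truth = generate_associations(
        SyntheticSpec(nd=10, nm=16, density=0.15, noise=0.0, seed=3)
    )
    return A, truth


@pytest.fixture
def fast_config():
    """Desk-scale configuration with few epochs for speed-sensitive tests."""
    return RunConfig(beta=2.0, lr=5e-3, dp_node=0.0, dp_reg=0.0,
                     epochs=30, k=16, seed=0)


def random_association(rng, nd, nm, p=0.35):
    """Random binary matrix with at least one 1 and one 0."""
    values = (rng.random((nd, nm)) < p).astype(float)
    if values.sum() == 0:
        values[rng.integers(nd), rng.integers(nm)] = 1.0
    if values.sum() == values.size:
        values[rng.integers(nd), rng.integers(nm)] = 0.0
    return AssociationMatrix(
        values,
        tuple(f"d{i}" for i in range(nd)),
        tuple(f"m{j}" for j in range(nm)),
    )
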