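import numpy as np
import pytest

from symptomnet import SymptomMatrix, SurrogateConfig, SymptomNetwork


@pytest.fixture
def rng():
    return np.random.default_rng(20240501)


@pytest.fixture
def tiny_matrix():
    """3 patients x 2 variables, hand-checkable."""
    return SymptomMatrix(
        np.array([[0, 1], [1, 1], [0, 0]]), ["tic_a", "tic_b"]
    )


@pytest.fixture
def random_matrix(rng):
    """60 patients x 5 variables of unstructured coin flips."""
    return SymptomMatrix(
        rng.integers(0, 2, size=(60, 5)), [f"v{i}" for i in range(5)]
    )


def make_network(weights, significant=None, names=None):
    """Assemble a SymptomNetwork directly from a weight matrix (tests only).

    Significance defaults to weight > 0; p-values are a monotone transform of
    the weights so FDR-related invariants stay meaningful.
    """
    weights = np.asarray(weights, dtype=float)
    k = weights.shape[0]
    if significant is None:
        significant = weights > 0
    significant = np.asarray(significant, dtype=bool)
    np.fill_diagonal(significant, False)
    pvalues = np.where(significant, 0.001, 1.0)
    np.fill_diagonal(pvalues, 1.0)
    if names is None:
        names = [f"n{i}" for i in range(k)]
    return SymptomNetwork(
        variable_names=list(names),
        weights=weights,
        pvalues=pvalues,
        significant=significant,
        config=SurrogateConfig(n_surrogates=100, seed=0),
    )


@pytest.fixture
def network_factory():
    return make_network
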