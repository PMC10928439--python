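import numpy as np
import pytest

from lepin import ComplexSet, WeightedPIN


@pytest.fixture
def worked_pin() -> WeightedPIN:
    """Four-node instance used throughout: a strong triangle {a,b,c} with
    a weak pendant d attached to c."""
    return WeightedPIN.from_edges(
        [("a", "b", 0.9), ("b", "c", 0.9), ("a", "c", 0.8), ("c", "d", 0.3)])


@pytest.fixture
def small_gold() -> ComplexSet:
    return ComplexSet.from_iterable([{"a", "b", "c"}, {"c", "d", "e"},
                                     {"f", "g"}])


class CentroidClassifier:
    """Cheap deterministic stand-in classifier for plumbing tests:
    probability = logistic distance to the positive-class centroid axis."""

    def __init__(self, seed: int = 0):
        self._w = None

    def fit(self, X, y):
        X = np.asarray(X, float)
        y = np.asarray(y).astype(bool)
        mu_pos = X[y].mean(axis=0)
        mu_neg = X[~y].mean(axis=0)
        self._w = mu_pos - mu_neg
        self._b = (mu_pos + mu_neg) / 2
        return self

    def predict_probability(self, X):
        z = (np.asarray(X, float) - self._b) @ self._w
        return 1.0 / (1.0 + np.exp(-20.0 * z))


@pytest.fixture
def centroid_factory():
    return lambda seed: CentroidClassifier(seed)
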