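import numpy as np
import pytest

from splinegraph.data import Dataset


@pytest.fixture
def gaussian_pair_data():
    """n=300 draws of a correlated Gaussian pair plus one noise column."""
    rng = np.random.default_rng(42)
    cov = np.array([[1.0, 0.7], [0.7, 1.0]])
    X = rng.multivariate_normal([0, 0], cov, 300)
    X = np.column_stack([X, rng.standard_normal(300)])
    return Dataset.from_array(X)


@pytest.fixture
def small_mixed_data():
    """Tiny mixed continuous/binary table for structural tests."""
    rng = np.random.default_rng(7)
    x = rng.random(40)
    b = (rng.random(40) < 0.5).astype(float)
    y = rng.random(40)
    return Dataset.from_array(np.column_stack([x, b, y]))
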