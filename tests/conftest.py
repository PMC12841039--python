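import numpy as np
import pytest

from zrank import ZMatrix


def zmatrix_from(values, genes=None, phenotypes=None) -> ZMatrix:
    values = np.atleast_2d(np.asarray(values, dtype=float))
    m, d = values.shape
    if genes is None:
        genes = tuple(f"g{i + 1:04d}" for i in range(m))
    if phenotypes is None:
        phenotypes = tuple(f"p{j + 1}" for j in range(d))
    return ZMatrix(genes=tuple(genes), phenotypes=tuple(phenotypes), values=values)


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def clean_bivariate():
    """5000 rows from N((1,2), [[1,.5],[.5,1]]) plus the generating parameters."""
    rng = np.random.default_rng(42)
    mu = np.array([1.0, 2.0])
    sigma = np.array([[1.0, 0.5], [0.5, 1.0]])
    X = mu + rng.standard_normal((5000, 2)) @ np.linalg.cholesky(sigma).T
    return zmatrix_from(X), mu, sigma
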