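import numpy as np
import pytest

from omitwas.preprocess import CountMatrix


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240)


def random_standardized(m, n, seed=0):
    """Rows with exact mean 0 and population variance 1."""
    r = np.random.default_rng(seed)
    Z = r.normal(size=(m, n))
    Z = Z - Z.mean(axis=1, keepdims=True)
    Z = Z / Z.std(axis=1, keepdims=True)
    return Z


def random_counts(m=200, n=6, seed=0, base=50.0, lib_sd=0.4):
    """Small Poisson-lognormal count matrix for normalization tests."""
    r = np.random.default_rng(seed)
    mu = base * np.exp(r.normal(0, 1.2, m))
    lib = np.exp(r.normal(0, lib_sd, n))
    counts = r.poisson(mu[:, None] * lib[None, :])
    return CountMatrix(
        [f"g{i:04d}" for i in range(m)], [f"s{j:02d}" for j in range(n)], counts
    )
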