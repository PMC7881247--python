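import numpy as np
import pytest

from pklreg import CountDataset, fit_pmle, spectral, weighted_crossproduct


def random_count_dataset(rng, n=40, p=3, beta_scale=0.4):
    """Small random Poisson dataset with moderate intensities."""
    X = np.column_stack([np.ones(n), rng.standard_normal((n, p))])
    beta = rng.normal(scale=beta_scale, size=p + 1)
    y = rng.poisson(np.exp(X @ beta))
    if np.all(y == 0):  # keep the MLE well defined
        y[0] = 1
    return CountDataset(X, y.astype(float)), beta


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def fitted(rng):
    """A converged fit on a moderately collinear dataset, with its spectrum."""
    n, p, rho = 80, 3, 0.9
    w = rng.standard_normal((n, p + 1))
    Xr = np.sqrt(1 - rho**2) * w[:, :p] + rho * w[:, [p]]
    X = np.column_stack([np.ones(n), Xr])
    beta = np.array([0.5, 0.4, 0.4, 0.4])
    y = rng.poisson(np.exp(X @ beta))
    data = CountDataset(X, y.astype(float))
    fit = fit_pmle(data)
    assert fit.converged
    G = weighted_crossproduct(data, fit)
    spec = spectral(G, fit)
    return data, fit, spec
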