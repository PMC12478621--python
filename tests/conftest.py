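"""Shared fixtures: small synthetic count matrices generated at test time."""

import numpy as np
import pytest

from cmpirt import cmp
from cmpirt.em import ItemParameters


def make_dataset(L, m, N, rho=0.0, seed=0, nu_override=None):
    """Simple-structure dataset straight from the generative model."""
    rng = np.random.default_rng(seed)
    M = L * m
    A = np.zeros((M, L))
    for l in range(L):
        A[l * m : (l + 1) * m, l] = np.linspace(0.2, 0.3, m)
    delta = np.linspace(1.5, 3.5, M)
    logdisp = np.linspace(-0.8, 0.8, M)
    if nu_override is not None:
        logdisp = np.full(M, np.log(nu_override))
    sigma = np.full((L, L), rho)
    np.fill_diagonal(sigma, 1.0)
    theta = rng.multivariate_normal(np.zeros(L), sigma, size=N)
    mu = np.exp(delta[None, :] + theta @ A.T)
    Y = np.empty((N, M), dtype=np.int64)
    for j in range(M):
        Y[:, j] = cmp.sample(mu[:, j], np.exp(logdisp[j]), N, rng)
    truth = ItemParameters(A, delta, logdisp)
    return Y, truth, sigma


@pytest.fixture(scope="session")
def small_dataset():
    """N=300, L=2, m=3 simple-structure counts with mixed dispersion."""
    return make_dataset(L=2, m=3, N=300, seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
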