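"""Multidimensional Gauss-Hermite quadrature and the EM E-step.

The latent traits follow MVN(0, Sigma) with unit diagonal.  The marginal
likelihood integral is approximated on a fixed tensor-product grid built
from probabilists' Gauss-Hermite rules, linearly mapped through the lower
Cholesky factor of Sigma.  Nodes whose product weight falls below a
truncation threshold are dropped and the remaining weights renormalized,
which keeps high-dimensional grids tractable.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp, gammaln

from cmpirt import cmp

__all__ = ["LatentCovariance", "QuadratureGrid", "build_grid", "e_step"]


@dataclass
class LatentCovariance:
    """Latent trait covariance matrix with unit diagonal (a correlation matrix)."""

    sigma: np.ndarray

    def __post_init__(self):
        s = np.asarray(self.sigma, dtype=float)
        if s.ndim != 2 or s.shape[0] != s.shape[1]:
            raise ValueError("sigma must be square")
        if not np.allclose(s, s.T, atol=1e-10):
            raise ValueError("sigma must be symmetric")
        if not np.allclose(np.diag(s), 1.0, atol=1e-10):
            raise ValueError("sigma must have unit diagonal (identification)")
        self.sigma = s

    @classmethod
    def identity(cls, L: int) -> "LatentCovariance":
        return cls(np.eye(L))

    @classmethod
    def exchangeable(cls, L: int, rho: float) -> "LatentCovariance":
        s = np.full((L, L), float(rho))
        np.fill_diagonal(s, 1.0)
        return cls(s)

    @property
    def L(self) -> int:
        return self.sigma.shape[0]

    def cholesky(self) -> np.ndarray:
        try:
            return np.linalg.cholesky(self.sigma)
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                "latent covariance is not positive definite"
            ) from err


@dataclass
class QuadratureGrid:
    """K multidimensional nodes with weights approximating MVN(0, Sigma)."""

    nodes: np.ndarray  # (K, L)
    weights: np.ndarray  # (K,)
    nodes_per_dim: int
    truncation_threshold: float = 0.0
    log_weights: np.ndarray = field(init=False)

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        self.log_weights = np.log(self.weights)

    @property
    def K(self) -> int:
        return self.nodes.shape[0]

    @property
    def L(self) -> int:
        return self.nodes.shape[1]


def default_nodes_per_dim(L: int) -> int:
    """Grid density falls with dimension to keep the tensor product tractable."""
    return 10 if L <= 3 else 4


def build_grid(
    L: int,
    nodes_per_dim: int,
    sigma: LatentCovariance,
    truncation_threshold: float = 1e-10,
) -> QuadratureGrid:
    """Tensor-product probabilists' Gauss-Hermite grid targeting MVN(0, Sigma).

    Univariate nodes/weights for the standard normal are tensored, the node
    matrix is mapped through the lower Cholesky factor of Sigma, low-weight
    nodes (< ``truncation_threshold``) are dropped, and weights renormalized
    to sum to one.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    if nodes_per_dim < 2:
        raise ValueError("nodes_per_dim must be >= 2")
    if sigma.L != L:
        raise ValueError("sigma dimension does not match L")
    # physicists' rule from numpy; rescale to the standard normal
    x, w = np.polynomial.hermite.hermgauss(nodes_per_dim)
    z = x * np.sqrt(2.0)
    wz = w / np.sqrt(np.pi)
    nodes1 = [z] * L
    grid = np.array(list(itertools.product(*nodes1)))
    wgrid = np.array([np.prod(c) for c in itertools.product(*([wz] * L))])
    keep = wgrid >= truncation_threshold
    grid, wgrid = grid[keep], wgrid[keep]
    chol = sigma.cholesky()
    nodes = grid @ chol.T
    wgrid = wgrid / wgrid.sum()
    return QuadratureGrid(
        nodes=nodes,
        weights=wgrid,
        nodes_per_dim=nodes_per_dim,
        truncation_threshold=truncation_threshold,
    )


def item_log_pmf_table(Y: np.ndarray, mu_nodes: np.ndarray, nu: np.ndarray):
    """Log CMP pmf of every response at every node: (N, M, K).

    ``mu_nodes`` is the (M, K) matrix of conditional means exp(delta_j +
    a_j' q_k); ``nu`` the M dispersions.  The per-(item, node) rate and
    normalizer are solved once and broadcast over persons.
    """
    N, M = Y.shape
    K = mu_nodes.shape[1]
    q = cmp.node_quantities(mu_nodes, nu[:, None], need_logfact=False)
    log_lam, log_z = q["log_lam"], q["log_z"]  # (M, K)
    lgy = gammaln(Y + 1.0)  # (N, M)
    # (N, M, K) = y * log_lam - nu * log y! - log Z
    return (
        Y[:, :, None] * log_lam[None, :, :]
        - nu[None, :, None] * lgy[:, :, None]
        - log_z[None, :, :]
    )


def loglik_matrix(Y, params, grid) -> np.ndarray:
    """(N, K) joint conditional log-likelihood of each person at each node."""
    mu_nodes = params.mu_nodes(grid)
    table = item_log_pmf_table(Y, mu_nodes, params.nu)
    out = table.sum(axis=1)
    if np.isnan(out).any():
        raise FloatingPointError("NaN in CMP likelihood at a quadrature node")
    return out


def e_step(Y: np.ndarray, params, grid: QuadratureGrid) -> np.ndarray:
    """Posterior node probabilities P(q_k | y_i): row-stochastic (N, K)."""
    ll = loglik_matrix(Y, params, grid) + grid.log_weights[None, :]
    ll -= logsumexp(ll, axis=1, keepdims=True)
    return np.exp(ll)


def marginal_loglik(Y, params, grid) -> float:
    """Quadrature-approximated observed-data (marginal) log-likelihood."""
    ll = loglik_matrix(Y, params, grid) + grid.log_weights[None, :]
    return float(logsumexp(ll, axis=1).sum())
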