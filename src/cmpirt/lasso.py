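"""Lasso-penalized EM for sparse discrimination matrices.

The M-step objective is the expected complete-data log-likelihood minus
``eta`` times the l1 norm of the free slopes (intercepts and dispersions
are never penalized).  Slopes are updated by item-blockwise coordinate
descent with soft-thresholding — the closed-form solution of each local
quadratic approximation — so estimates hit exactly zero, unlike rotated
solutions.  The penalty weight ``eta`` is tuned on a log-equidistant grid
by BIC, where the BIC uses the *unpenalized* marginal log-likelihood at the
penalized estimates and counts only parameters neither shrunken nor
constrained to zero.  Fits along the grid are warm-started from the
previous solution; the eta = 0 entry starts from the unpenalized fit and
converges immediately.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

from cmpirt import em as _em
from cmpirt.em import (
    ConstraintMask,
    FitConfig,
    FitResult,
    ItemParameters,
    apply_constraints,
    gradients,
)
from cmpirt.quadrature import (
    LatentCovariance,
    build_grid,
    default_nodes_per_dim,
    e_step,
    marginal_loglik,
)
from cmpirt.rotation import oblimin

__all__ = [
    "soft_threshold",
    "cd_mstep",
    "fit_lasso",
    "bic",
    "eta_max_kkt",
    "tune_path",
    "sigma_plugin",
    "PenaltyPath",
]


def soft_threshold(z: float, t: float):
    """S(z, t) = sign(z) * max(|z| - t, 0)."""
    if np.any(np.asarray(t) < 0):
        raise ValueError("threshold must be nonnegative")
    return np.sign(z) * np.maximum(np.abs(z) - t, 0.0)


def cd_mstep(Y, params, post, grid, mask, eta, config: Optional[FitConfig] = None):
    """One penalized M-step: coordinate-descent slopes/intercepts, then a
    dispersion Newton update, per item.  ``eta = 0`` reproduces the
    unpenalized M-step."""
    return _em.m_step(Y, params, post, grid, mask, config, eta=eta)


def fit_lasso(
    Y,
    L: int,
    sigma: Optional[LatentCovariance] = None,
    eta: float = 0.0,
    start: Optional[ItemParameters] = None,
    config: Optional[FitConfig] = None,
    mask: Optional[ConstraintMask] = None,
) -> FitResult:
    """EM with the lasso M-step at fixed penalty weight ``eta``."""
    if eta < 0:
        raise ValueError("eta must be nonnegative")
    Y = np.asarray(Y, dtype=float)
    M = Y.shape[1]
    config = config or FitConfig()
    sigma = sigma or LatentCovariance.identity(L)
    mask = mask or apply_constraints(L, M)
    grid = build_grid(
        L, config.nodes_per_dim or default_nodes_per_dim(L), sigma,
        config.truncation_threshold,
    )
    if start is None:
        start = _em.fit_poisson_start(Y, L, mask, grid, config)
    params = start.copy()
    params.slopes[mask.fixed_zero] = 0.0
    params, it, converged, trace = _em._em_loop(
        Y, params, grid, mask, config, eta=eta
    )
    return FitResult(
        params=params,
        marginal_loglik=marginal_loglik(Y, params, grid),
        n_iter=it,
        converged=converged,
        grid=grid,
        sigma=sigma,
        loglik_trace=trace,
        n_obs=Y.shape[0],
    )


def bic(fit: FitResult, mask: ConstraintMask):
    """BIC(eta) = -2 l(theta_hat) + log(N) df.

    ``l`` is the unpenalized quadrature-approximated marginal log-likelihood
    at the (possibly penalized) estimates; ``df`` counts free nonzero slopes
    plus all intercepts and all dispersions.
    """
    p = fit.params
    df = int(np.count_nonzero(p.slopes[mask.free()])) + 2 * p.M
    value = -2.0 * fit.marginal_loglik + np.log(fit.n_obs) * df
    return float(value), df


def eta_max_kkt(Y, L, sigma=None, config=None, mask=None, start=None) -> float:
    """Penalty weight at which the lasso update zeroes every free slope.

    The KKT condition for an all-zero free-slope M-step solution is
    |dQ/da_jl| <= eta for every free entry.  The gradient is evaluated at
    zero slopes under the posterior implied by the Poisson warm start (or a
    supplied ``start``): with a degenerate flat posterior the slope score
    vanishes identically (zero slopes make the traits unidentifiable), so
    the informative warm-start posterior is the meaningful reference point.
    """
    Y = np.asarray(Y, dtype=float)
    M = Y.shape[1]
    config = config or FitConfig()
    sigma = sigma or LatentCovariance.identity(L)
    mask = mask or apply_constraints(L, M)
    grid = build_grid(
        L, config.nodes_per_dim or default_nodes_per_dim(L), sigma,
        config.truncation_threshold,
    )
    if start is None:
        start = _em.fit_poisson_start(Y, L, mask, grid, config)
    post = e_step(Y, start, grid)
    at_zero = start.copy()
    at_zero.slopes[:] = 0.0
    g = gradients(Y, at_zero, post, grid)
    return float(np.abs(g.d_slopes[mask.free()]).max())


@dataclass
class PenaltyPath:
    """A regularization path: per-eta fits, BIC values, and the selection."""

    etas: np.ndarray
    fits: List[FitResult]
    bics: np.ndarray
    dfs: np.ndarray
    selected: int
    mask: ConstraintMask = None

    @property
    def selected_fit(self) -> FitResult:
        return self.fits[self.selected]

    def summary(self):
        import pandas as pd

        rows = []
        for i, (eta, f) in enumerate(zip(self.etas, self.fits)):
            rows.append(
                {
                    "eta": eta,
                    "bic": self.bics[i],
                    "df": self.dfs[i],
                    "loglik": f.marginal_loglik,
                    "n_iter": f.n_iter,
                    "converged": f.converged,
                    "n_zero_slopes": int(
                        np.sum(f.params.slopes[self.mask.free()] == 0.0)
                    ),
                    "selected": i == self.selected,
                }
            )
        return pd.DataFrame(rows)


def default_eta_grid(eta_max: float, n: int = 12) -> np.ndarray:
    """0 followed by n log-equidistant values from eta_max/1000 to eta_max."""
    grid = np.geomspace(eta_max / 1000.0, eta_max, n)
    return np.concatenate([[0.0], grid])


def tune_path(
    Y,
    L: int,
    sigma: Optional[LatentCovariance] = None,
    eta_grid=None,
    config: Optional[FitConfig] = None,
    mask: Optional[ConstraintMask] = None,
    n_grid: int = 12,
    unpenalized: Optional[FitResult] = None,
) -> PenaltyPath:
    """Fit the whole penalty path with warm starts and select by BIC.

    The eta = 0 entry is started from the unpenalized fit (fitted here if
    not supplied), each subsequent eta from the previous solution.  Ties in
    BIC resolve to the smallest eta.  Per-eta failures are recorded and the
    path continues.
    """
    Y = np.asarray(Y, dtype=float)
    config = config or FitConfig()
    sigma = sigma or LatentCovariance.identity(L)
    mask = mask or apply_constraints(L, Y.shape[1])
    if unpenalized is None:
        unpenalized = _em.fit(Y, L, sigma=sigma, config=config, mask=mask)
    if eta_grid is None:
        eta_grid = default_eta_grid(
            eta_max_kkt(Y, L, sigma=sigma, config=config, mask=mask), n_grid
        )
    eta_grid = np.sort(np.asarray(eta_grid, dtype=float))
    if eta_grid[0] != 0.0:
        raise ValueError("eta grid must start at (or include) 0")
    fits, bics, dfs = [], [], []
    start = unpenalized.params
    for eta in eta_grid:
        try:
            f = fit_lasso(
                Y, L, sigma=sigma, eta=float(eta), start=start,
                config=config, mask=mask,
            )
            b, df = bic(f, mask)
            start = f.params
        except FloatingPointError:
            f, b, df = None, np.inf, -1
        fits.append(f)
        bics.append(b)
        dfs.append(df)
    bics = np.asarray(bics)
    dfs = np.asarray(dfs)
    selected = int(np.flatnonzero(bics <= bics.min() + 1e-9)[0])
    return PenaltyPath(
        etas=eta_grid, fits=fits, bics=bics, dfs=dfs, selected=selected, mask=mask
    )


def sigma_plugin(A_unpenalized: np.ndarray) -> LatentCovariance:
    """Latent correlation matrix from oblique rotation of the unpenalized
    discrimination matrix (the two-step treatment of correlated traits).

    Falls back to the nearest correlation matrix if the rotation's Phi is
    numerically indefinite.
    """
    rot = oblimin(np.asarray(A_unpenalized, dtype=float))
    phi = (rot.phi + rot.phi.T) / 2.0
    np.fill_diagonal(phi, 1.0)
    eigvals = np.linalg.eigvalsh(phi)
    if eigvals.min() <= 1e-10:
        from statsmodels.stats.correlation_tools import corr_nearest

        phi = corr_nearest(phi, threshold=1e-6)
        np.fill_diagonal(phi, 1.0)
    return LatentCovariance(phi)
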