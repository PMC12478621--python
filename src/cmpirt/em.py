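"""Marginal maximum likelihood for the multidimensional CMP response model.

Model: person i with latent trait vector theta_i ~ MVN(0, Sigma) responds to
item j with a count y_ij ~ CMP(mu_ij, nu_j) in the mean parameterization,
where log mu_ij = delta_j + a_j' theta_i.  The slopes a_jl are the
discrimination parameters, delta_j the intercepts, and nu_j item-specific
dispersions optimized on the log scale.

Estimation is EM over a fixed Gauss-Hermite grid: the E-step computes
posterior node probabilities, the M-step maximizes the expected
complete-data log-likelihood Q item by item with damped Newton coordinate
updates (the same engine, with a soft-threshold bolted on, drives the lasso
variant in :mod:`cmpirt.lasso`).

Gradient algebra.  With node means mu_jk, variances V_jk, third central
moments kappa3_jk and the log-factorial expectations A_jk = E[log Y!],
C_jk = Cov(Y, log Y!) of the node CMP laws, and posterior sufficient
statistics n_k = sum_i p_ik, ybar_jk = sum_i p_ik y_ij,
g_jk = sum_i p_ik log(y_ij!):

    dQ/d delta_j = sum_k (ybar_jk - n_k mu_jk) mu_jk / V_jk
    dQ/d a_jl    = sum_k (ybar_jk - n_k mu_jk) mu_jk q_kl / V_jk
    dQ/d log nu_j = nu_j sum_k [ (ybar_jk - n_k mu_jk) C_jk / V_jk
                                 - (g_jk - n_k A_jk) ]

The slope/intercept curvatures follow from d mu / d eta = mu and
d V / d mu = kappa3 / V (exponential-family cumulant identities):

    w_jk = (ybar_jk - n_k mu_jk) (mu_jk / V_jk - mu_jk^2 kappa3_jk / V_jk^3)
           - n_k mu_jk^2 / V_jk
    d2Q/d delta_j^2 = sum_k w_jk,      d2Q/d a_jl^2 = sum_k w_jk q_kl^2

All of these are verified against finite differences of Q in the test
suite; that agreement is the anchor for the whole M-step.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
from scipy.special import gammaln

from cmpirt import cmp
from cmpirt.quadrature import (
    LatentCovariance,
    QuadratureGrid,
    build_grid,
    default_nodes_per_dim,
    e_step,
    marginal_loglik,
)

__all__ = [
    "ItemParameters",
    "ConstraintMask",
    "FitConfig",
    "FitResult",
    "GradientBundle",
    "apply_constraints",
    "expected_cdll",
    "gradients",
    "m_step",
    "fit_poisson_start",
    "fit",
    "read_counts_csv",
]


@dataclass
class ItemParameters:
    """Discrimination matrix, intercepts and log-dispersions for M items."""

    slopes: np.ndarray  # (M, L)
    intercepts: np.ndarray  # (M,)
    log_disp: np.ndarray  # (M,)

    def __post_init__(self):
        self.slopes = np.atleast_2d(np.asarray(self.slopes, dtype=float))
        self.intercepts = np.asarray(self.intercepts, dtype=float)
        self.log_disp = np.asarray(self.log_disp, dtype=float)

    @property
    def M(self) -> int:
        return self.slopes.shape[0]

    @property
    def L(self) -> int:
        return self.slopes.shape[1]

    @property
    def nu(self) -> np.ndarray:
        return np.exp(self.log_disp)

    def mu_nodes(self, grid: QuadratureGrid) -> np.ndarray:
        """(M, K) conditional means exp(delta_j + a_j' q_k)."""
        return np.exp(self.intercepts[:, None] + self.slopes @ grid.nodes.T)

    def copy(self) -> "ItemParameters":
        return ItemParameters(
            self.slopes.copy(), self.intercepts.copy(), self.log_disp.copy()
        )

    def flat(self) -> np.ndarray:
        return np.concatenate(
            [self.slopes.ravel(), self.intercepts, self.log_disp]
        )

    def to_dict(self) -> dict:
        return {
            "slopes": self.slopes.tolist(),
            "intercepts": self.intercepts.tolist(),
            "log_disp": self.log_disp.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ItemParameters":
        return cls(
            np.array(d["slopes"]), np.array(d["intercepts"]), np.array(d["log_disp"])
        )


@dataclass
class ConstraintMask:
    """Boolean (M, L) matrix of slope entries fixed to exactly zero."""

    fixed_zero: np.ndarray

    def __post_init__(self):
        self.fixed_zero = np.atleast_2d(np.asarray(self.fixed_zero, dtype=bool))

    @property
    def n_constraints(self) -> int:
        return int(self.fixed_zero.sum())

    def free(self) -> np.ndarray:
        return ~self.fixed_zero


def apply_constraints(L: int, M: int, scheme="echelon") -> ConstraintMask:
    """Identification mask removing rotational indeterminacy.

    Default echelon scheme: in the leading L-1 items, item j (1-based) is
    free on its first j traits and fixed to zero on the rest, giving
    L(L-1)/2 fixed zeros (an upper-triangular block of zeros).  A custom
    boolean matrix may be passed for confirmatory-style patterns.
    """
    if M < L:
        raise ValueError("need at least as many items as traits")
    if isinstance(scheme, str):
        if scheme != "echelon":
            raise ValueError(f"unknown constraint scheme {scheme!r}")
        mask = np.zeros((M, L), dtype=bool)
        for j in range(L - 1):
            mask[j, j + 1 :] = True
    else:
        mask = np.atleast_2d(np.asarray(scheme, dtype=bool))
        if mask.shape != (M, L):
            raise ValueError("custom mask has wrong shape")
    if (mask.all(axis=0)).any():
        raise ValueError("a trait with an all-zero column is unidentified")
    return ConstraintMask(mask)


@dataclass
class FitConfig:
    """Numerical knobs for the EM fits."""

    nodes_per_dim: Optional[int] = None  # default: 10 for L <= 3, else 4
    truncation_threshold: float = 1e-10
    tol: float = 1e-4  # max-abs parameter change stopping rule
    max_iter: int = 1000
    inner_tol: float = 1e-6  # per-item M-step stopping rule
    inner_max_iter: int = 2
    cd_tol: float = 1e-6  # coordinate-sweep stopping rule (lasso M-step)
    cd_max_sweeps: int = 100
    max_step_halvings: int = 30


@dataclass
class FitResult:
    """A converged (or flagged non-converged) EM fit."""

    params: ItemParameters
    marginal_loglik: float
    n_iter: int
    converged: bool
    grid: QuadratureGrid
    sigma: LatentCovariance
    loglik_trace: list = field(default_factory=list)
    n_obs: int = 0

    def to_json(self, config: Optional[FitConfig] = None) -> str:
        payload = {
            "params": self.params.to_dict(),
            "marginal_loglik": self.marginal_loglik,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "sigma": self.sigma.sigma.tolist(),
            "loglik_trace": list(self.loglik_trace),
        }
        if config is not None:
            payload["config"] = asdict(config)
        return json.dumps(payload, indent=2)


@dataclass
class GradientBundle:
    """First and (diagonal) second derivatives of Q in all item parameters."""

    d_slopes: np.ndarray  # (M, L)
    d_intercepts: np.ndarray  # (M,)
    d_logdisp: np.ndarray  # (M,)
    h_slopes: np.ndarray  # (M, L)
    h_intercepts: np.ndarray  # (M,)
    work_w: np.ndarray  # (M, K) per-(item, node) curvature working quantity


# ---------------------------------------------------------------------------
# sufficient statistics and node-law quantities


def _suffstats(Y: np.ndarray, post: np.ndarray):
    """Posterior-weighted sufficient statistics: n_k, ybar_jk, g_jk."""
    n_k = post.sum(axis=0)  # (K,)
    ybar = Y.T @ post  # (M, K)
    glg = gammaln(Y + 1.0).T @ post  # (M, K)
    return n_k, ybar, glg


def _node_laws(mu, nu, poisson: bool, need_logfact: bool):
    """CMP law quantities at node means; closed forms in the Poisson case."""
    if poisson:
        out = {
            "log_lam": np.log(mu),
            "log_z": mu,
            "var": mu,
            "kappa3": mu,
        }
        if need_logfact:
            q = cmp.node_quantities(mu, np.ones_like(np.asarray(mu, float)))
            out["e_logfact"] = q["e_logfact"]
            out["cov_y_logfact"] = q["cov_y_logfact"]
        return out
    return cmp.node_quantities(mu, nu, need_logfact=need_logfact)


def expected_cdll(Y, params: ItemParameters, post, grid: QuadratureGrid) -> float:
    """Expected complete-data log-likelihood Q (sums additively over items)."""
    n_k, ybar, glg = _suffstats(Y, post)
    mu = params.mu_nodes(grid)
    laws = _node_laws(mu, params.nu[:, None], poisson=False, need_logfact=False)
    q = (
        ybar * laws["log_lam"]
        - params.nu[:, None] * glg
        - n_k[None, :] * laws["log_z"]
    ).sum()
    if np.isnan(q):
        raise FloatingPointError("NaN in expected complete-data log-likelihood")
    return float(q)


def gradients(Y, params: ItemParameters, post, grid: QuadratureGrid) -> GradientBundle:
    """Analytic first and diagonal second derivatives of Q (all items at once)."""
    n_k, ybar, glg = _suffstats(Y, post)
    nu = params.nu
    mu = params.mu_nodes(grid)
    laws = _node_laws(mu, nu[:, None], poisson=False, need_logfact=True)
    V, k3 = laws["var"], laws["kappa3"]
    resid = ybar - n_k[None, :] * mu  # (M, K)
    score = resid * mu / V  # (M, K)
    d_int = score.sum(axis=1)
    d_slopes = score @ grid.nodes  # (M, L)
    d_logdisp = nu * (
        (resid * laws["cov_y_logfact"] / V).sum(axis=1)
        - (glg - n_k[None, :] * laws["e_logfact"]).sum(axis=1)
    )
    w = resid * (mu / V - mu**2 * k3 / V**3) - n_k[None, :] * mu**2 / V
    h_int = w.sum(axis=1)
    h_slopes = w @ grid.nodes**2
    return GradientBundle(
        d_slopes=d_slopes,
        d_intercepts=d_int,
        d_logdisp=d_logdisp,
        h_slopes=h_slopes,
        h_intercepts=h_int,
        work_w=w,
    )


# ---------------------------------------------------------------------------
# M-step engine (shared by unpenalized and lasso updates)
#
# The expected complete-data log-likelihood decomposes over items, and each
# coordinate update touches only its own item's row, so every coordinate of
# every item can be updated in one vectorized pass over the (M, K) table of
# node CMP laws.  Rate solves are warm-started from the previous table.


class _MStepState:
    """Vectorized working state of one M-step across all M items."""

    def __init__(self, Y, post, grid, mask, poisson=False):
        self.n_k, self.ybar, glg = _suffstats(Y, post)
        self.glg_sum = glg.sum(axis=1)  # (M,)
        self.nodes = grid.nodes  # (K, L)
        self.free = mask.free()  # (M, L)
        self.poisson = poisson
        self._log_lam = None

    def laws(self, delta, A, nu, need_logfact=False):
        mu = np.exp(delta[:, None] + A @ self.nodes.T)  # (M, K)
        if self.poisson:
            laws = _node_laws(mu, 1.0, True, need_logfact)
        else:
            laws = cmp.node_quantities(
                mu, nu[:, None], need_logfact=need_logfact, log_lam0=self._log_lam
            )
            self._log_lam = laws["log_lam"]
        laws["mu"] = mu
        return laws

    def q_items(self, laws, nu):
        """Per-item expected complete-data log-likelihood contributions."""
        return (
            (self.ybar * laws["log_lam"]).sum(axis=1)
            - nu * self.glg_sum
            - laws["log_z"] @ self.n_k
        )

    def grad_curv(self, laws, x_k):
        """Per-item gradient and curvature along direction weights x_k (K,)."""
        mu, V, k3 = laws["mu"], laws["var"], laws["kappa3"]
        resid = self.ybar - self.n_k[None, :] * mu
        score = resid * mu / V
        w = resid * (mu / V - mu**2 * k3 / V**3) - self.n_k[None, :] * mu**2 / V
        return score @ x_k, w @ x_k**2

    def disp_grad(self, delta, A, nu, laws=None):
        if laws is None:
            laws = self.laws(delta, A, nu, need_logfact=True)
        resid = self.ybar - self.n_k[None, :] * laws["mu"]
        return nu * (
            (resid * laws["cov_y_logfact"] / laws["var"]).sum(axis=1)
            - (self.glg_sum - laws["e_logfact"] @ self.n_k)
        )


def _soft(z, t):
    return np.sign(z) * np.maximum(np.abs(z) - t, 0.0)


def _penalty(A, free, eta):
    return eta * np.abs(np.where(free, A, 0.0)).sum(axis=1)


def _update_coordinate(state, delta, A, nu, coord, eta, config, laws=None):
    """Damped-Newton (or soft-thresholded) update of one coordinate for all
    items simultaneously, with per-item step-halving on the penalized Q.

    Returns the updated parameters, the largest coordinate move, and (when
    available) the node-law table at the accepted point so the next
    coordinate can skip recomputing it.
    """
    if laws is None:
        laws = state.laws(delta, A, nu)
    if coord == "delta":
        x_k = np.ones(state.nodes.shape[0])
        x_old = delta
        active = np.ones(A.shape[0], dtype=bool)
    else:
        x_k = state.nodes[:, coord]
        x_old = A[:, coord].copy()
        active = state.free[:, coord]
    g, h = state.grad_curv(laws, x_k)
    if np.any(~np.isfinite(h[active])) or np.any(h[active] >= 0):
        raise FloatingPointError(
            "non-negative curvature in coordinate update (CMP numeric failure)"
        )
    d = np.where(active, -h, 1.0)  # inactive rows never move; avoid 0/NaN
    if coord != "delta" and eta > 0:
        x_new = _soft(x_old + g / d, eta / d)
    else:
        x_new = x_old + g / d
    step = np.where(active, x_new - x_old, 0.0)
    if np.max(np.abs(step), initial=0.0) < 1e-9:
        # negligible move: accept without the safeguard evaluation
        return delta, A, float(np.max(np.abs(step), initial=0.0)), laws
    q_old = state.q_items(laws, nu) - _penalty(A, state.free, eta)
    # moves below the rate-solver noise floor are accepted outright
    tiny = np.abs(step) < 1e-8
    x_cur = np.where(active & tiny, x_old + step, x_old)
    pending = active & ~tiny
    laws_out = None
    for _ in range(config.max_step_halvings):
        if not pending.any():
            break
        x_try = np.where(pending, x_old + step, x_cur)
        if coord == "delta":
            laws_t = state.laws(x_try, A, nu)
            q_new = state.q_items(laws_t, nu) - _penalty(A, state.free, eta)
        else:
            A_try = A.copy()
            A_try[:, coord] = x_try
            laws_t = state.laws(delta, A_try, nu)
            q_new = state.q_items(laws_t, nu) - _penalty(A_try, state.free, eta)
        ok = q_new >= q_old - 1e-10 * np.maximum(1.0, np.abs(q_old))
        x_cur = np.where(pending & ok, x_try, x_cur)
        if ok[pending].all():
            laws_out = laws_t  # table already sits at the accepted point
        pending = pending & ~ok
        step = np.where(pending, 0.5 * step, step)
        # halved into the noise floor: keep the old value and move on
        drop = pending & (np.abs(step) < 1e-8)
        pending = pending & ~drop
    if pending.any():
        raise FloatingPointError("step halving failed 30 times in the M-step")
    if coord == "delta":
        delta = x_cur
    else:
        A[:, coord] = x_cur
    return delta, A, float(np.max(np.abs(x_cur - x_old), initial=0.0)), laws_out


def _update_dispersion(state, delta, A, log_nu, config, fd_step=1e-4):
    """One safeguarded Newton update of all log-dispersions.

    Gradients are analytic; the curvature is a central difference of the
    analytic gradient (the third-order log-factorial cross-moments an exact
    curvature would need are not worth their numerical surface area).
    """
    nu0 = np.exp(log_nu)
    laws0 = state.laws(delta, A, nu0, need_logfact=True)
    g = state.disp_grad(delta, A, nu0, laws=laws0)
    gp = state.disp_grad(delta, A, np.exp(log_nu + fd_step))
    h = (gp - g) / fd_step
    step = np.where(h < 0, np.clip(-g / np.where(h < 0, h, -1.0), -0.5, 0.5),
                    np.clip(0.1 * g, -0.5, 0.5))
    q_old = state.q_items(laws0, nu0)
    tiny = np.abs(step) < 1e-8
    cur = np.where(tiny, log_nu + step, log_nu)
    pending = ~tiny
    for _ in range(config.max_step_halvings):
        if not pending.any():
            break
        trial = np.where(pending, log_nu + step, cur)
        nu_t = np.exp(trial)
        q_new = state.q_items(state.laws(delta, A, nu_t), nu_t)
        ok = q_new >= q_old - 1e-10 * np.maximum(1.0, np.abs(q_old))
        cur = np.where(pending & ok, trial, cur)
        pending = pending & ~ok
        step = np.where(pending, 0.5 * step, step)
        drop = pending & (np.abs(step) < 1e-8)
        pending = pending & ~drop
    return cur, np.max(np.abs(cur - log_nu), initial=0.0)


def m_step(
    Y,
    params: ItemParameters,
    post,
    grid: QuadratureGrid,
    mask: ConstraintMask,
    config: Optional[FitConfig] = None,
    eta: float = 0.0,
    update_disp: bool = True,
    poisson: bool = False,
) -> ItemParameters:
    """Item-blockwise maximization of Q honoring the identification mask.

    ``eta > 0`` turns the slope updates into soft-thresholded lasso updates
    (used by :mod:`cmpirt.lasso`); ``eta = 0`` is the plain damped-Newton
    maximizer.  Q is non-decreasing by the per-coordinate step-halving
    safeguard.
    """
    config = config or FitConfig()
    new = params.copy()
    new.slopes[mask.fixed_zero] = 0.0
    state = _MStepState(Y, post, grid, mask, poisson)
    delta, A, log_nu = new.intercepts, new.slopes, new.log_disp
    L = A.shape[1]
    for _ in range(config.inner_max_iter):
        change = 0.0
        laws = None
        for _ in range(config.cd_max_sweeps):
            sweep_change = 0.0
            for coord in list(range(L)) + ["delta"]:
                delta, A, c, laws = _update_coordinate(
                    state, delta, A, np.exp(log_nu), coord, eta, config, laws=laws
                )
                sweep_change = max(sweep_change, c)
            change = max(change, sweep_change)
            if sweep_change < config.cd_tol:
                break
        if update_disp and not poisson:
            log_nu, c = _update_dispersion(state, delta, A, log_nu, config)
            change = max(change, c)
        if change < config.inner_tol:
            break
    new.intercepts, new.slopes, new.log_disp = delta, A, log_nu
    return new


# ---------------------------------------------------------------------------
# full fits


def _em_loop(Y, params, grid, mask, config, eta=0.0, update_disp=True, poisson=False):
    trace = []
    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        post = e_step(Y, params, grid)
        new = m_step(
            Y, params, post, grid, mask, config, eta=eta,
            update_disp=update_disp, poisson=poisson,
        )
        change = np.max(np.abs(new.flat() - params.flat()))
        params = new
        trace.append(marginal_loglik(Y, params, grid))
        if change < config.tol:
            converged = True
            break
    return params, it, converged, trace


def fit_poisson_start(
    Y, L: int, mask: ConstraintMask, grid: QuadratureGrid,
    config: Optional[FitConfig] = None,
) -> ItemParameters:
    """Multidimensional two-parameter Poisson fit plus dispersion starts.

    The Poisson EM (nu fixed at 1) is cheap because all CMP quantities are
    closed-form.  Log-dispersion starts are moment-based: minus the log of
    the posterior-weighted mean squared Pearson residual per item, clipped
    to [-2, 2] (equidispersed data give ~0, overdispersed negative starts).
    """
    config = config or FitConfig()
    Y = np.asarray(Y, dtype=float)
    M = Y.shape[1]
    col_mean = np.clip(Y.mean(axis=0), 1e-3, None)
    params = ItemParameters(
        slopes=np.full((M, L), 0.1),
        intercepts=np.log(col_mean),
        log_disp=np.zeros(M),
    )
    params.slopes[mask.fixed_zero] = 0.0
    pois_cfg = FitConfig(
        tol=max(config.tol, 1e-3),
        max_iter=min(config.max_iter, 200),
        inner_tol=config.inner_tol,
        inner_max_iter=config.inner_max_iter,
        max_step_halvings=config.max_step_halvings,
    )
    params, _, _, _ = _em_loop(
        Y, params, grid, mask, pois_cfg, update_disp=False, poisson=True
    )
    # moment-based dispersion starts from the Poisson posterior
    post = e_step(Y, params, grid)
    mu = params.mu_nodes(grid)  # (M, K)
    disp_index = np.einsum("ik,ijk->j", post, (Y[:, :, None] - mu[None]) ** 2 / mu[None])
    disp_index /= Y.shape[0]
    params.log_disp = np.clip(-np.log(np.clip(disp_index, 1e-6, None)), -2.0, 2.0)
    return params


def fit(
    Y,
    L: int,
    sigma: Optional[LatentCovariance] = None,
    config: Optional[FitConfig] = None,
    mask: Optional[ConstraintMask] = None,
    start: Optional[ItemParameters] = None,
) -> FitResult:
    """Unpenalized marginal ML fit of the multidimensional CMP model.

    Poisson warm start, then full EM alternation until the maximum absolute
    parameter change drops below ``config.tol``.  Non-convergence is
    reported through ``FitResult.converged`` rather than an exception.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2 or Y.shape[0] < 2:
        raise ValueError("Y must be an N x M matrix with N >= 2")
    if np.any(Y < 0) or np.any(Y != np.round(Y)):
        raise ValueError("Y must contain nonnegative integer counts")
    M = Y.shape[1]
    if M < L:
        raise ValueError("need at least as many items as traits")
    config = config or FitConfig()
    sigma = sigma or LatentCovariance.identity(L)
    mask = mask or apply_constraints(L, M)
    npd = config.nodes_per_dim or default_nodes_per_dim(L)
    grid = build_grid(L, npd, sigma, config.truncation_threshold)
    params = start.copy() if start is not None else fit_poisson_start(
        Y, L, mask, grid, config
    )
    params.slopes[mask.fixed_zero] = 0.0
    params, it, converged, trace = _em_loop(Y, params, grid, mask, config)
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


def read_counts_csv(path) -> np.ndarray:
    """Read a persons x items count matrix from CSV (header row required).

    A leading non-numeric id column is detected and dropped.  Non-integer
    cells raise a clear error.
    """
    import pandas as pd

    df = pd.read_csv(path)
    if df.shape[1] > 1:
        first = df.iloc[:, 0]
        if first.dtype == object or first.name.lower() in {"id", "person"}:
            df = df.iloc[:, 1:]
    arr = df.to_numpy()
    try:
        arr = arr.astype(float)
    except (TypeError, ValueError) as err:
        raise ValueError(f"non-numeric cell in counts CSV: {err}") from err
    if np.any(arr != np.round(arr)) or np.any(arr < 0):
        raise ValueError("counts CSV must contain nonnegative integers only")
    return arr.astype(np.int64)
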