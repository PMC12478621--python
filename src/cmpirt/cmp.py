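"""Mean-parameterized Conway-Maxwell-Poisson (CMP) distribution.

The CMP pmf with rate ``lam`` and dispersion ``nu`` is

    P(Y = y) = lam**y / (y!)**nu / Z(lam, nu),     y = 0, 1, 2, ...

where ``Z`` is the normalizing series ``sum_y lam**y / (y!)**nu``.  In the
mean parameterization the user supplies the conditional mean ``mu`` and the
rate is obtained by solving ``E[Y; lam, nu] = mu`` for ``lam``.  ``nu = 1``
recovers the Poisson distribution; ``nu > 1`` gives underdispersion
(``Var < mu``) and ``nu < 1`` overdispersion (``Var > mu``).

Everything is computed by direct, numerically robust summation of the series
in log space.  Viewed as an exponential family in the natural parameter
``theta = log lam`` (sufficient statistic ``y``, carrier ``(y!)**-nu``), the
cumulant derivatives give ``d mean / d theta = Var`` and
``d Var / d theta = kappa3`` (third central moment), which is what the
rate solver and the model Hessians rely on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.special import gammaln

__all__ = [
    "CMPParams",
    "log_normalizer",
    "solve_rate",
    "log_pmf",
    "moments",
    "sample",
    "node_quantities",
]

_MAX_TERMS = 10_000  # hard series cap; the 1e-12 relative term rule stops earlier


class CMPSeriesError(RuntimeError):
    """Normalizer series failed to converge within the term cap."""


_LGY = gammaln(np.arange(_MAX_TERMS + 1) + 1.0)


@njit(cache=True, fastmath=True)
def _series_kernel(log_lam, nu, lgy, need_logfact, max_terms):  # pragma: no cover
    """Per-point summation of the CMP series in mode-anchored scale.

    Columns of the output: log_z, m1, m2, m3 (raw Y moments), E[log Y!],
    E[Y log Y!], number of terms used, tail-failure flag.  Summation stops
    once the current term falls below 1e-12 of the running sum past the
    mode, or at ``max_terms`` (flagged as failure).
    """
    n = log_lam.shape[0]
    out = np.zeros((n, 8))
    for i in range(n):
        ll, v = log_lam[i], nu[i]
        mode = math.exp(min(ll / v, math.log(max_terms)))
        t0 = mode * ll - v * math.lgamma(mode + 1.0)
        z = 0.0
        s1 = 0.0
        s2 = 0.0
        s3 = 0.0
        sl = 0.0
        syl = 0.0
        used = max_terms
        failed = 1.0
        for y in range(max_terms):
            w = math.exp(ll * y - v * lgy[y] - t0)
            z += w
            yy = float(y)
            s1 += w * yy
            s2 += w * yy * yy
            s3 += w * yy * yy * yy
            if need_logfact:
                sl += w * lgy[y]
                syl += w * yy * lgy[y]
            if yy > mode and w < 1e-12 * z:
                used = y + 1
                failed = 0.0
                break
        out[i, 0] = math.log(z) + t0
        out[i, 1] = s1 / z
        out[i, 2] = s2 / z
        out[i, 3] = s3 / z
        out[i, 4] = sl / z
        out[i, 5] = syl / z
        out[i, 6] = used
        out[i, 7] = failed
    return out


def _series_sums(log_lam, nu, need_logfact=False, max_terms=_MAX_TERMS):
    """Summation of the CMP series and its moments (vectorized over points).

    Parameters are 1-d arrays of equal length.  Returns a dict with
    ``log_z``, raw moment sums ``m1``, ``m2``, ``m3`` (of Y), optionally
    ``e_logfact`` = E[log Y!] and ``e_y_logfact`` = E[Y log Y!], plus the
    number of terms used.  All expectations are exact up to the 1e-12
    relative term-size truncation rule.
    """
    log_lam = np.ascontiguousarray(log_lam, dtype=float)
    nu = np.ascontiguousarray(nu, dtype=float)
    r = _series_kernel(log_lam, nu, _LGY, need_logfact, max_terms)
    if r[:, 7].any():
        i = int(np.argmax(r[:, 7]))
        raise CMPSeriesError(
            f"CMP normalizer series did not converge within {max_terms} terms "
            f"(log_lam={log_lam[i]:.3g}, nu={nu[i]:.3g})"
        )
    out = {
        "log_z": r[:, 0],
        "m1": r[:, 1],
        "m2": r[:, 2],
        "m3": r[:, 3],
        "n_terms": r[:, 6].astype(int),
    }
    if need_logfact:
        out["e_logfact"] = r[:, 4]
        out["e_y_logfact"] = r[:, 5]
    return out


def log_normalizer(lam: float, nu: float, max_terms: int = _MAX_TERMS):
    """Log of the CMP normalizing constant ``Z(lam, nu)``.

    Returns ``(log_z, series_len)`` where ``series_len`` is the number of
    series terms summed.  Raises :class:`CMPSeriesError` if the series does
    not satisfy the truncation rule within ``max_terms`` terms.
    """
    if lam <= 0 or nu <= 0:
        raise ValueError("lam and nu must be positive")
    s = _series_sums(np.array([np.log(lam)]), np.array([nu]), max_terms=max_terms)
    return float(s["log_z"][0]), int(s["n_terms"][0])


def _solve_log_rate(
    mu: np.ndarray, nu: np.ndarray, tol=1e-10, max_iter=100, t0=None,
    return_stats=False,
):
    """Vectorized Newton solve (in log lam) of E[Y; lam, nu] = mu.

    d mean / d log lam = Var > 0, so the map is strictly increasing and
    Newton from the Shmueli-style approximation ``lam ~ (mu + (nu-1)/(2 nu))**nu``
    converges quickly; a bisection fallback guards pathological cases.  An
    optional warm start ``t0`` (log rates from a nearby solve) cuts the
    iteration count when called repeatedly along an optimization path.
    """
    mu = np.asarray(mu, dtype=float)
    nu = np.asarray(nu, dtype=float)
    if t0 is not None:
        t = np.array(t0, dtype=float, copy=True)
    else:
        shifted = np.maximum(mu + (nu - 1.0) / (2.0 * nu), mu / 2.0)
        t = nu * np.log(shifted)
    # Poisson shortcut
    pois = np.isclose(nu, 1.0, atol=0.0, rtol=1e-14)
    t = np.where(pois, np.log(mu), t)
    free = ~pois
    if not free.any():
        return (t, None) if return_stats else t
    idx = np.flatnonzero(free)
    tf = t[idx]
    muf, nuf = mu[idx], nu[idx]
    converged = False
    for _ in range(max_iter):
        s = _series_sums(tf, nuf)
        resid = s["m1"] - muf
        if np.all(np.abs(resid) <= tol * np.maximum(1.0, muf)):
            converged = True
            break
        var = np.maximum(s["m2"] - s["m1"] ** 2, 1e-300)
        step = np.clip(resid / var, -5.0, 5.0)
        tf = tf - step
    if not converged:
        # bisection fallback for any stragglers
        s = _series_sums(tf, nuf)
        bad = np.abs(s["m1"] - muf) > 1e-8 * np.maximum(1.0, muf)
        for j in np.flatnonzero(bad):
            tf[j] = _bisect_log_rate(muf[j], nuf[j])
    t[idx] = tf
    if return_stats:
        if pois.any() or not converged:
            return t, None  # stats stale or incomplete; caller recomputes
        stats = s
        return t, stats
    return t


def _bisect_log_rate(mu: float, nu: float, max_iter=200) -> float:
    lo, hi = np.log(1e-8), np.log(1e8)
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        m = _series_sums(np.array([mid]), np.array([nu]))["m1"][0]
        if abs(m - mu) <= 1e-12 * max(1.0, mu):
            return mid
        if m < mu:
            lo = mid
        else:
            hi = mid
    raise CMPSeriesError(f"rate solve failed for mu={mu}, nu={nu}")


def solve_rate(mu: float, nu: float) -> float:
    """Rate ``lam`` such that the CMP(lam, nu) mean equals ``mu``."""
    if mu <= 0 or nu <= 0:
        raise ValueError("mu and nu must be positive")
    return float(np.exp(_solve_log_rate(np.array([mu]), np.array([nu]))[0]))


@dataclass
class CMPParams:
    """One mean-parameterized CMP: mean, dispersion, implied rate and variance."""

    mu: float
    nu: float
    lam: float
    var: float
    series_len: int

    @classmethod
    def from_mean(cls, mu: float, nu: float) -> "CMPParams":
        log_lam = _solve_log_rate(np.array([mu]), np.array([nu]))
        s = _series_sums(log_lam, np.array([nu]))
        return cls(
            mu=float(mu),
            nu=float(nu),
            lam=float(np.exp(log_lam[0])),
            var=float(s["m2"][0] - s["m1"][0] ** 2),
            series_len=int(s["n_terms"][0]),
        )


def log_pmf(y, params: CMPParams) -> np.ndarray:
    """Log pmf ``y log lam - nu log y! - log Z`` at nonnegative integers y."""
    y = np.asarray(y, dtype=float)
    log_z, _ = log_normalizer(params.lam, params.nu)
    return y * np.log(params.lam) - params.nu * gammaln(y + 1.0) - log_z


def moments(mu: float, nu: float):
    """Variance, E[log Y!] and E[Y log Y!] of the mean-parameterized CMP."""
    log_lam = _solve_log_rate(np.array([mu]), np.array([nu]))
    s = _series_sums(log_lam, np.array([nu]), need_logfact=True)
    var = float(s["m2"][0] - s["m1"][0] ** 2)
    return var, float(s["e_logfact"][0]), float(s["e_y_logfact"][0])


def sample(mu, nu, n: int, seed) -> np.ndarray:
    """Draw ``n`` i.i.d. counts by inverse-CDF over the truncated pmf.

    ``mu``/``nu`` may be scalars (n i.i.d. draws) or length-n arrays (one
    draw per element, used by the response generator).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mu = np.broadcast_to(np.asarray(mu, dtype=float), (n,)).copy()
    nu = np.broadcast_to(np.asarray(nu, dtype=float), (n,))
    # group identical (mu, nu) pairs so the pmf is built once per pair
    pairs = np.stack([mu, nu], axis=1)
    uniq, inv = np.unique(pairs, axis=0, return_inverse=True)
    out = np.empty(n, dtype=np.int64)
    u = rng.random(n)
    for g in range(uniq.shape[0]):
        gm, gn = uniq[g]
        log_lam = _solve_log_rate(np.array([gm]), np.array([gn]))[0]
        s = _series_sums(np.array([log_lam]), np.array([gn]))
        cap = int(s["n_terms"][0])
        yy = np.arange(cap + 1, dtype=float)
        logp = yy * log_lam - gn * gammaln(yy + 1.0) - s["log_z"][0]
        cdf = np.cumsum(np.exp(logp))
        # truncate where cumulative mass reaches 1 - 1e-10
        stop = int(np.searchsorted(cdf, 1.0 - 1e-10)) + 1
        cdf = cdf[:stop]
        sel = inv == g
        out[sel] = np.searchsorted(cdf, u[sel])
    return out


def node_quantities(mu, nu, need_logfact=True, log_lam0=None):
    """Vectorized per-(mu, nu) quantities consumed by the EM gradients.

    Returns a dict with ``log_lam``, ``log_z``, ``var``, ``kappa3`` (third
    central moment, = d Var / d log lam), and — when ``need_logfact`` —
    ``e_logfact`` and ``cov_y_logfact`` = Cov(Y, log Y!).  Shapes follow the
    broadcast shape of ``mu`` and ``nu``.
    """
    mu = np.asarray(mu, dtype=float)
    nu_b = np.broadcast_to(np.asarray(nu, dtype=float), mu.shape)
    shape = mu.shape
    mu_f = mu.reshape(-1)
    nu_f = nu_b.reshape(-1).copy()
    t0 = None if log_lam0 is None else np.asarray(log_lam0, dtype=float).reshape(-1)
    log_lam, s = _solve_log_rate(mu_f, nu_f, t0=t0, return_stats=True)
    if s is None or need_logfact:
        s = _series_sums(log_lam, nu_f, need_logfact=need_logfact)
    m1, m2, m3 = s["m1"], s["m2"], s["m3"]
    var = m2 - m1**2
    kappa3 = m3 - 3.0 * m1 * m2 + 2.0 * m1**3
    out = {
        "log_lam": log_lam.reshape(shape),
        "log_z": s["log_z"].reshape(shape),
        "var": var.reshape(shape),
        "kappa3": kappa3.reshape(shape),
    }
    if need_logfact:
        out["e_logfact"] = s["e_logfact"].reshape(shape)
        out["cov_y_logfact"] = (s["e_y_logfact"] - m1 * s["e_logfact"]).reshape(shape)
    return out
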