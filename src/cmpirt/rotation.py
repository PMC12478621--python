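"""Factor rotation of the discrimination matrix via gradient projection.

After an exploratory fit under the echelon identification constraint, the
discrimination matrix is only determined up to rotation.  This module
implements the two classical criteria the field reaches for:

* varimax — orthogonal; maximizes the variance of squared loadings within
  columns,
* oblimin (default gamma = 0, i.e. quartimin) — oblique; minimizes the
  cross-column covariance of squared loadings and yields a factor
  correlation matrix Phi.

Both run on a single gradient-projection algorithm (GPA; orthogonal and
oblique variants) with seeded random restarts, since rotation criteria are
multimodal.  Conventions: orthogonal Lambda_rot = A T with T orthogonal;
oblique Lambda_rot = A (T')^{-1} with unit-norm columns of T and
Phi = T' T.  In both cases Lambda_rot Phi Lambda_rot' equals A A', the
rotation-invariant Gram matrix the evaluation metrics consume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["RotationResult", "varimax", "oblimin", "align_columns", "align_solution"]


@dataclass
class RotationResult:
    loadings: np.ndarray  # (M, L) rotated matrix
    rot: np.ndarray  # (L, L) rotation matrix T
    phi: np.ndarray  # (L, L) factor correlations (identity if orthogonal)
    criterion: float
    converged: bool


def _vgq_varimax(L):
    """Negative varimax criterion and gradient (minimization form)."""
    Q = L**2
    C = Q - Q.mean(axis=0, keepdims=True)
    f = -np.sum(Q * C) / 4.0
    Gq = -L * C
    return f, Gq


def _vgq_oblimin(L, gamma=0.0):
    """Oblimin family criterion and gradient; gamma = 0 is quartimin."""
    M, k = L.shape
    Q = L**2
    N = np.ones((k, k)) - np.eye(k)
    if gamma != 0:
        J = np.eye(M) - gamma / M * np.ones((M, M))
        X = J @ Q @ N
    else:
        X = Q @ N
    f = np.sum(Q * X) / 4.0
    Gq = L * X
    return f, Gq


def _gpa_orth(A, vgq, T0, max_iter=1000, tol=1e-6):
    T = T0.copy()
    al = 1.0
    Lr = A @ T
    f, Gq = vgq(Lr)
    G = A.T @ Gq
    for _ in range(max_iter):
        M = T.T @ G
        S = (M + M.T) / 2.0
        Gp = G - T @ S
        s = np.linalg.norm(Gp)
        if s < tol:
            return T, f, True
        al = 2.0 * al
        for _ in range(60):
            X = T - al * Gp
            U, _, Vt = np.linalg.svd(X)
            Tt = U @ Vt
            Lr = A @ Tt
            ft, Gq = vgq(Lr)
            if ft < f - 0.5 * s**2 * al:
                break
            al /= 2.0
        T = Tt
        f = ft
        G = A.T @ Gq
    return T, f, False


def _gpa_oblq(A, vgq, T0, max_iter=1000, tol=1e-6):
    T = T0.copy()
    al = 1.0
    Ti = np.linalg.inv(T)
    Lr = A @ Ti.T
    f, Gq = vgq(Lr)
    G = -(Lr.T @ Gq @ Ti).T
    for _ in range(max_iter):
        Gp = G - T * np.diag(T.T @ G)[None, :]
        s = np.linalg.norm(Gp)
        if s < tol:
            return T, f, True
        al = 2.0 * al
        for _ in range(60):
            X = T - al * Gp
            X = X / np.sqrt((X**2).sum(axis=0, keepdims=True))
            Ti = np.linalg.inv(X)
            Lr = A @ Ti.T
            ft, Gq = vgq(Lr)
            if ft < f - 0.5 * s**2 * al:
                break
            al /= 2.0
        T = X
        f = ft
        G = -(Lr.T @ Gq @ Ti).T
    return T, f, False


def _random_orth(L, rng):
    q, r = np.linalg.qr(rng.standard_normal((L, L)))
    return q * np.sign(np.diag(r))


def varimax(A: np.ndarray, n_restarts: int = 10, seed: int = 0) -> RotationResult:
    """Varimax rotation by orthogonal GPA with random restarts."""
    A = np.asarray(A, dtype=float)
    if A.shape[1] < 2:
        raise ValueError("rotation needs at least two factors")
    rng = np.random.default_rng(seed)
    best = None
    for r in range(n_restarts):
        T0 = np.eye(A.shape[1]) if r == 0 else _random_orth(A.shape[1], rng)
        T, f, conv = _gpa_orth(A, _vgq_varimax, T0)
        if best is None or f < best[1]:
            best = (T, f, conv)
    T, f, conv = best
    return RotationResult(
        loadings=A @ T,
        rot=T,
        phi=np.eye(A.shape[1]),
        criterion=float(f),
        converged=bool(conv),
    )


def oblimin(
    A: np.ndarray, gamma: float = 0.0, n_restarts: int = 10, seed: int = 0
) -> RotationResult:
    """Oblimin (quartimin by default) rotation by oblique GPA."""
    A = np.asarray(A, dtype=float)
    if A.shape[1] < 2:
        raise ValueError("rotation needs at least two factors")
    rng = np.random.default_rng(seed)
    vgq = lambda L: _vgq_oblimin(L, gamma)  # noqa: E731
    best = None
    for r in range(n_restarts):
        T0 = np.eye(A.shape[1]) if r == 0 else _random_orth(A.shape[1], rng)
        T, f, conv = _gpa_oblq(A, vgq, T0)
        if best is None or f < best[1]:
            best = (T, f, conv)
    T, f, conv = best
    phi = T.T @ T
    return RotationResult(
        loadings=A @ np.linalg.inv(T).T,
        rot=T,
        phi=phi,
        criterion=float(f),
        converged=bool(conv),
    )


def align_columns(A_hat: np.ndarray, A_ref: np.ndarray):
    """Greedy column permutation/sign alignment of an estimate to a reference.

    Trait labels and signs are arbitrary in exploratory models; alignment by
    maximal absolute Tucker congruence makes estimates comparable to a
    simulation truth.  Returns (aligned matrix, permutation, signs).
    """
    A_hat = np.asarray(A_hat, dtype=float)
    A_ref = np.asarray(A_ref, dtype=float)
    L = A_hat.shape[1]
    denom = np.outer(
        np.sqrt((A_hat**2).sum(axis=0) + 1e-300),
        np.sqrt((A_ref**2).sum(axis=0) + 1e-300),
    )
    congr = np.abs(A_hat.T @ A_ref) / denom  # (L_hat, L_ref)
    perm = np.full(L, -1)
    used = set()
    for _ in range(L):
        c = congr.copy()
        for i in range(L):
            if perm[i] >= 0:
                c[i, :] = -1
        c[:, list(used)] = -1
        i, r = np.unravel_index(np.argmax(c), c.shape)
        perm[i] = r
        used.add(r)
    order = np.argsort(perm)  # column of A_hat assigned to ref column r
    aligned = A_hat[:, order]
    signs = np.sign((aligned * A_ref).sum(axis=0))
    signs[signs == 0] = 1.0
    return aligned * signs[None, :], order, signs


def align_solution(A_hat, phi_hat, A_ref):
    """Align loadings and factor correlations jointly to a reference.

    The same permutation and sign flips applied to the loading columns are
    applied congruently to Phi, leaving the Gram matrix A Phi A' unchanged.
    """
    aligned, order, signs = align_columns(A_hat, A_ref)
    phi = np.asarray(phi_hat, dtype=float)[np.ix_(order, order)]
    phi = phi * np.outer(signs, signs)
    return aligned, phi
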