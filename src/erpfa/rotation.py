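"""Geomin rotation by gradient projection.

The Geomin criterion for a p x m loading matrix L is

    f(L) = sum_t [ prod_j (L_tj^2 + eps) ]^(1/m)

— the row-wise geometric mean of squared loadings, softened by a small
eps > 0.  Small values reward simple structure (each time point loaded by
few factors).  Minimisation over oblique (or orthogonal) transforms of an
initial loading matrix uses the gradient-projection algorithm with Armijo
backtracking, so the criterion is non-increasing across iterations.

Multiple random starts guard against local minima: start 1 is the identity
transform, subsequent starts are random orthonormal matrices drawn from a
seeded generator; the best (lowest-criterion) converged start wins, ties
broken by lowest start index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["geomin_rotate", "geomin_criterion", "RotationError", "RotationResult"]


class RotationError(RuntimeError):
    pass


def geomin_criterion(L: np.ndarray, eps: float):
    """Criterion value and its gradient with respect to L."""
    L = np.asarray(L, dtype=float)
    m = L.shape[1]
    L2 = L * L + eps
    pro = np.exp(np.log(L2).sum(axis=1) / m)
    f = float(pro.sum())
    G = (2.0 / m) * (L / L2) * pro[:, None]
    return f, G


def _gpa_oblique(A, T0, eps, tol, max_iter):
    """Oblique gradient projection (unit-length transform columns)."""
    T = T0.copy()
    Ti = np.linalg.inv(T)
    L = A @ Ti.T
    f, Gq = geomin_criterion(L, eps)
    G = -(L.T @ Gq @ Ti).T
    al = 1.0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        Gp = G - T * (T * G).sum(axis=0)
        s2 = float((Gp * Gp).sum())
        al *= 2.0
        ft, Lt, Tit, Tt = f, L, Ti, T
        for _ in range(30):
            X = T - al * Gp
            v = 1.0 / np.sqrt((X * X).sum(axis=0))
            Tt = X * v
            try:
                Tit = np.linalg.inv(Tt)
            except np.linalg.LinAlgError:
                al /= 2.0
                continue
            Lt = A @ Tit.T
            ft, Gqt = geomin_criterion(Lt, eps)
            if ft < f - 0.5 * s2 * al:
                break
            al /= 2.0
        df = f - ft
        T, Ti, L, f = Tt, Tit, Lt, ft
        _, Gq = geomin_criterion(L, eps)
        G = -(L.T @ Gq @ Ti).T
        if df < tol:
            converged = True
            break
    Phi = T.T @ T
    return L, Phi, f, converged, it


def _gpa_orthogonal(A, T0, eps, tol, max_iter):
    T = T0.copy()
    L = A @ T
    f, Gq = geomin_criterion(L, eps)
    G = A.T @ Gq
    al = 1.0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        M = T.T @ G
        Gp = G - T @ (M + M.T) / 2.0
        s2 = float((Gp * Gp).sum())
        al *= 2.0
        ft, Lt, Tt = f, L, T
        for _ in range(30):
            X = T - al * Gp
            U, _, Vt = np.linalg.svd(X)
            Tt = U @ Vt
            Lt = A @ Tt
            ft, Gqt = geomin_criterion(Lt, eps)
            if ft < f - 0.5 * s2 * al:
                break
            al /= 2.0
        df = f - ft
        T, L, f = Tt, Lt, ft
        _, Gq = geomin_criterion(L, eps)
        G = A.T @ Gq
        if df < tol:
            converged = True
            break
    Phi = np.eye(T.shape[1])
    return L, Phi, f, converged, it


def _lbfgs_oblique(A, T0, eps, max_iter=1500):
    """Quasi-Newton acceleration on the column-normalized transform.

    Parameterizes T = V / ||V_j|| and minimizes f(A (T^-1)') with the
    analytic gradient; used to traverse the flat regions of the criterion
    (many near-zero noise factors) that slow plain gradient projection,
    after which the projection iteration certifies the optimum.
    """
    from scipy import optimize

    m = T0.shape[0]

    def fg(v):
        V = v.reshape(m, m)
        nrm = np.sqrt((V * V).sum(axis=0))
        if np.any(nrm < 1e-12):
            return 1e12, np.zeros(m * m)
        T = V / nrm
        try:
            Ti = np.linalg.inv(T)
        except np.linalg.LinAlgError:
            return 1e12, np.zeros(m * m)
        L = A @ Ti.T
        f, Gq = geomin_criterion(L, eps)
        GT = -(L.T @ Gq @ Ti).T
        GV = (GT - T * (T * GT).sum(axis=0)) / nrm
        return f, GV.ravel()

    res = optimize.minimize(
        fg,
        T0.ravel(),
        jac=True,
        method="L-BFGS-B",
        options=dict(maxiter=max_iter, ftol=1e-12, gtol=1e-8),
    )
    V = res.x.reshape(m, m)
    nrm = np.sqrt((V * V).sum(axis=0))
    if np.any(nrm < 1e-12) or not np.isfinite(res.fun):
        return T0
    return V / nrm


@dataclass
class RotationResult:
    loadings: np.ndarray
    phi: np.ndarray
    criterion: float
    best_start: int
    start_log: list[dict] = field(default_factory=list)
    config: dict = field(default_factory=dict)


def _random_orthonormal(rng, m):
    Q, R = np.linalg.qr(rng.standard_normal((m, m)))
    return Q * np.sign(np.diag(R))


def geomin_rotate(
    loadings0: np.ndarray,
    eps: float = 0.01,
    n_starts: int = 30,
    seed: int | None = 0,
    oblique: bool = True,
    tol: float = 1e-7,
    max_iter: int = 1000,
) -> RotationResult:
    """Best-of-starts Geomin rotation of an unrotated loading matrix.

    Defaults follow the analysis convention: eps = 0.01, 30 random starts,
    oblique (factor correlations estimated).  For m = 1 the identity
    rotation is returned with Phi = [[1]].
    """
    A = np.asarray(loadings0, dtype=float)
    if A.ndim != 2 or A.shape[1] < 1:
        raise RotationError("loadings must be a p x m matrix with m >= 1")
    if eps <= 0:
        raise RotationError("eps must be positive")
    m = A.shape[1]
    config = dict(eps=eps, n_starts=n_starts, seed=seed, oblique=oblique, tol=tol)
    if m == 1:
        f, _ = geomin_criterion(A, eps)
        return RotationResult(A.copy(), np.eye(1), f, 0, [dict(start=0, criterion=f, converged=True)], config)

    rng = np.random.default_rng(seed)
    log = []
    best = None
    for s in range(n_starts):
        T0 = np.eye(m) if s == 0 else _random_orthonormal(rng, m)
        if oblique:
            T0 = _lbfgs_oblique(A, T0, eps)
            L, Phi, f, converged, iters = _gpa_oblique(A, T0, eps, tol, max_iter)
        else:
            L, Phi, f, converged, iters = _gpa_orthogonal(A, T0, eps, tol, max_iter)
        log.append(dict(start=s, criterion=f, converged=converged, iterations=iters))
        if not converged:
            continue
        if best is None or f < best[0] - 1e-8:
            best = (f, L, Phi, s)
    if best is None:
        raise RotationError("no rotation start converged")
    f, L, Phi, s = best
    return RotationResult(L, Phi, f, s, log, config)
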