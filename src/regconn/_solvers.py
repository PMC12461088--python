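"""Penalized precision-matrix solvers.

Both solvers target the Gaussian log-likelihood with a penalty on the
off-diagonal precision entries only (the diagonal is never penalized):

    minimize_P  -log det P + tr(S P) + penalty(P_offdiag)

with an L1 penalty (lasso) or a squared-L2 penalty (ridge). The lasso is
solved by proximal gradient descent with Barzilai-Borwein steps and a
backtracking line search that keeps iterates positive definite. The ridge
stationarity condition P^{-1} = S - 2*l2*diag(P) + 2*l2*P is solved exactly
in the eigenbasis of the shifted covariance for a fixed diagonal and
iterated on the diagonal, which converges in a handful of passes.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import cho_factor, cho_solve


class SolverNonConvergence(RuntimeError):
    """Raised when a penalized-likelihood solver fails to reach tolerance."""

    def __init__(self, message, n_iter=None, max_change=None):
        super().__init__(message)
        self.n_iter = n_iter
        self.max_change = max_change


def glasso(
    S: np.ndarray,
    lambda1: float,
    precision_init: np.ndarray | None = None,
    tol: float = 1e-5,
    max_iter: int = 10_000,
    raise_on_nonconvergence: bool = True,
):
    """L1-penalized (off-diagonal) maximum-likelihood precision estimation.

    Parameters
    ----------
    S : (p, p) sample covariance/correlation matrix.
    lambda1 : penalty weight on sum_{i != j} |P_ij|.
    precision_init : optional warm start (must be positive definite).
    tol : convergence threshold on the max absolute change per iterate.

    Returns
    -------
    (P, info) with P the estimated precision and info a diagnostics dict.
    """
    if lambda1 < 0:
        raise ValueError("lambda1 must be >= 0")
    p = S.shape[0]
    I = np.eye(p)
    if precision_init is not None:
        P = np.array(precision_init, dtype=float, copy=True)
    else:
        P = np.diag(1.0 / np.clip(np.diag(S), 1e-12, None)).copy()
    cf = cho_factor(P, lower=True, check_finite=False)
    Pinv = cho_solve(cf, I, check_finite=False)
    smooth = -2.0 * np.log(np.diag(cf[0])).sum() + (S * P).sum()
    G = S - Pinv
    t = 1.0
    max_change = np.inf
    for it in range(1, max_iter + 1):
        while True:
            C = P - t * G
            d = np.diag(C).copy()
            Pn = np.sign(C) * np.maximum(np.abs(C) - t * lambda1, 0.0)
            np.fill_diagonal(Pn, d)
            try:
                cf = cho_factor(Pn, lower=True, check_finite=False)
            except np.linalg.LinAlgError:
                t *= 0.5
                if t < 1e-14:
                    raise SolverNonConvergence(
                        "graphical lasso line search collapsed", it, max_change
                    )
                continue
            smooth_new = -2.0 * np.log(np.diag(cf[0])).sum() + (S * Pn).sum()
            D = Pn - P
            upper = smooth + (G * D).sum() + (D * D).sum() / (2.0 * t)
            if smooth_new <= upper + 1e-10:
                break
            t *= 0.5
            if t < 1e-14:
                raise SolverNonConvergence(
                    "graphical lasso line search collapsed", it, max_change
                )
        Pinv_n = cho_solve(cf, I, check_finite=False)
        Gn = S - Pinv_n
        dG = Gn - G
        denom = (D * dG).sum()
        if denom > 1e-30:
            t = (D * D).sum() / denom
        max_change = float(np.abs(D).max())
        P, Pinv, G, smooth = Pn, Pinv_n, Gn, smooth_new
        if max_change < tol:
            return P, {"n_iter": it, "max_change": max_change, "converged": True}
    if raise_on_nonconvergence:
        raise SolverNonConvergence(
            f"graphical lasso did not converge in {max_iter} iterations "
            f"(last max change {max_change:.2e}, tol {tol:.2e})",
            max_iter,
            max_change,
        )
    return P, {"n_iter": max_iter, "max_change": max_change, "converged": False}


def gridge(
    S: np.ndarray,
    lambda2: float,
    tol: float = 1e-8,
    max_iter: int = 200,
    diag_init: np.ndarray | None = None,
):
    """Off-diagonal L2-penalized maximum-likelihood precision estimation.

    For a fixed diagonal correction the stationarity condition is the
    quadratic matrix equation mu*P^2 + A*P - I = 0 with mu = 2*lambda2 and
    A = S - mu*diag(P), solved exactly through the eigendecomposition of A;
    the diagonal is then updated until self-consistent.
    """
    if lambda2 < 0:
        raise ValueError("lambda2 must be >= 0")
    p = S.shape[0]
    if lambda2 == 0:
        P = np.linalg.inv(S)
        return P, {"n_iter": 0, "max_change": 0.0, "converged": True}
    mu = 2.0 * lambda2
    d = np.zeros(p) if diag_init is None else np.asarray(diag_init, dtype=float).copy()
    P = None
    hist: list[np.ndarray] = []
    for it in range(1, max_iter + 1):
        A = S - np.diag(mu * d)
        w, Q = np.linalg.eigh(A)
        phi = (-w + np.sqrt(w * w + 4.0 * mu)) / (2.0 * mu)
        P = (Q * phi) @ Q.T
        d_new = np.diag(P).copy()
        change = float(np.max(np.abs(d_new - d)))
        if change < tol:
            return P, {"n_iter": it, "max_change": change, "converged": True}
        hist.append(d_new)
        if len(hist) >= 3 and it % 3 == 0:
            # componentwise Aitken extrapolation of the linearly converging
            # diagonal sequence; safeguarded against tiny denominators
            d0, d1, d2 = hist[-3], hist[-2], hist[-1]
            den = d2 - 2.0 * d1 + d0
            d = d2.copy()
            mask = np.abs(den) > 1e-12
            d[mask] = d2[mask] - (d2[mask] - d1[mask]) ** 2 / den[mask]
        else:
            d = d_new
    raise SolverNonConvergence(
        f"graphical ridge fixed point did not converge in {max_iter} iterations",
        max_iter,
        change,
    )


def precision_to_partial(P: np.ndarray) -> np.ndarray:
    """Partial correlations r_ij|C = -P_ij / sqrt(P_ii P_jj), zero diagonal."""
    d = np.sqrt(np.diag(P))
    R = -P / np.outer(d, d)
    np.fill_diagonal(R, 0.0)
    return (R + R.T) / 2.0
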