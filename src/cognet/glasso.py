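"""Graphical lasso: L1-penalized sparse precision-matrix estimation.

Solves, for a sample correlation/covariance matrix ``S`` and penalty
``lam >= 0``::

    maximize_K  log det K - tr(S K) - lam * sum_{i != j} |K_ij|

over positive-definite ``K`` (the diagonal is not penalized, the usual
convention for correlation inputs).  The solver is the block coordinate
descent of the classic algorithm: each column of the working covariance
``W`` is updated by an inner lasso regression solved by coordinate
descent.  Compiled with numba so that resampling procedures (bootstrap,
case-drop, permutation) can re-estimate thousands of small networks;
warm starts across a decreasing penalty path make path fitting cheap.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _glasso_cd(S, lam, W, B, tol, max_iter, inner_tol, inner_max):
    """One glasso solve, updating W (covariance) and B (lasso coefs)
    in place.  Returns the iteration count (== max_iter if the W-change
    criterion was never met)."""
    p = S.shape[0]
    it = 0
    for it in range(1, max_iter + 1):
        max_delta = 0.0
        for j in range(p):
            beta = B[:, j]
            for _ in range(inner_max):
                delta_in = 0.0
                for k in range(p):
                    if k == j:
                        continue
                    acc = 0.0
                    for l in range(p):
                        if l == j or l == k:
                            continue
                        acc += W[k, l] * beta[l]
                    u = S[k, j] - acc
                    if u > lam:
                        new = (u - lam) / W[k, k]
                    elif u < -lam:
                        new = (u + lam) / W[k, k]
                    else:
                        new = 0.0
                    d = abs(new - beta[k])
                    if d > delta_in:
                        delta_in = d
                    beta[k] = new
                if delta_in < inner_tol:
                    break
            for k in range(p):
                if k == j:
                    continue
                acc = 0.0
                for l in range(p):
                    if l == j:
                        continue
                    acc += W[k, l] * beta[l]
                d = abs(acc - W[k, j])
                if d > max_delta:
                    max_delta = d
                W[k, j] = acc
                W[j, k] = acc
        if max_delta < tol:
            break
    return it


@njit(cache=True)
def _recover_precision(W, B):
    p = W.shape[0]
    K = np.zeros((p, p))
    for j in range(p):
        acc = 0.0
        for l in range(p):
            if l != j:
                acc += W[j, l] * B[l, j]
        kjj = 1.0 / (W[j, j] - acc)
        K[j, j] = kjj
        for l in range(p):
            if l != j:
                K[l, j] = -B[l, j] * kjj
    # column-wise recovery is asymmetric only up to solver tolerance
    return 0.5 * (K + K.T)


class GlassoNonConvergence(RuntimeError):
    """Raised when block coordinate descent fails to converge."""


def glasso_fit(
    S: np.ndarray,
    lam: float,
    *,
    tol: float = 1e-6,
    max_iter: int = 500,
    warm: tuple[np.ndarray, np.ndarray] | None = None,
) -> np.ndarray:
    """Fit one penalized precision matrix.

    Parameters
    ----------
    S : symmetric positive-semidefinite matrix (correlation scale).
    lam : penalty on off-diagonal precision entries; ``lam = 0`` gives
        the unpenalized inverse (S must then be invertible).
    warm : optional ``(W, B)`` state from a previous fit at a nearby
        penalty, modified in place.

    Returns the estimated precision matrix.
    """
    S = np.asarray(S, dtype=np.float64)
    p = S.shape[0]
    if S.shape != (p, p) or not np.allclose(S, S.T, atol=1e-10):
        raise ValueError("S must be a symmetric square matrix")
    if lam < 0:
        raise ValueError("penalty must be >= 0")
    if lam == 0.0:
        K = np.linalg.inv(S)
        return 0.5 * (K + K.T)
    if warm is None:
        W = S.copy()
        B = np.zeros((p, p))
    else:
        W, B = warm
    n_iter = _glasso_cd(S, lam, W, B, tol, max_iter, tol * 0.1, 200)
    if n_iter >= max_iter:
        raise GlassoNonConvergence(
            f"glasso did not converge in {max_iter} iterations "
            f"(p={p}, lam={lam:.4g}); max W-change above {tol:g}"
        )
    return _recover_precision(W, B)


def glasso_path(
    S: np.ndarray,
    lams: np.ndarray,
    *,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> np.ndarray:
    """Fit a decreasing penalty path with warm starts.

    ``lams`` must be sorted in decreasing order.  Returns an array of
    shape ``(len(lams), p, p)`` of precision estimates.
    """
    S = np.asarray(S, dtype=np.float64)
    p = S.shape[0]
    lams = np.asarray(lams, dtype=np.float64)
    if np.any(np.diff(lams) > 0):
        raise ValueError("penalty path must be non-increasing")
    out = np.empty((len(lams), p, p))
    W = S.copy()
    B = np.zeros((p, p))
    for i, lam in enumerate(lams):
        out[i] = glasso_fit(
            S, float(lam), tol=tol, max_iter=max_iter, warm=(W, B)
        )
    return out


def glasso_objective(K: np.ndarray, S: np.ndarray, lam: float) -> float:
    """Penalized negative log-likelihood (up to constants):
    ``-log det K + tr(S K) + lam * sum_{i!=j} |K_ij|``."""
    sign, logdet = np.linalg.slogdet(K)
    if sign <= 0:
        return np.inf
    penalty = lam * (np.abs(K).sum() - np.abs(np.diag(K)).sum())
    return float(-logdet + np.trace(S @ K) + penalty)
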