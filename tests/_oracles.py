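"""Independent oracles used by the tests.

These deliberately avoid the package's own code paths: the penalized
precision objective is minimized by a restarted derivative-free
optimizer, and graph centralities are computed by exhaustive simple-
path enumeration.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import minimize


def penalized_objective(K: np.ndarray, S: np.ndarray, lam: float) -> float:
    sign, logdet = np.linalg.slogdet(K)
    if sign <= 0:
        return np.inf
    pen = lam * (np.abs(K).sum() - np.abs(np.diag(K)).sum())
    return float(-logdet + np.trace(S @ K) + pen)


def glasso_oracle_objective(
    S: np.ndarray, lam: float, restarts: int = 8
) -> float:
    """Minimum of the penalized negative log-likelihood found by
    restarted Nelder-Mead over the upper triangle of K."""
    p = S.shape[0]
    iu = np.triu_indices(p)

    def f(theta):
        K = np.zeros((p, p))
        K[iu] = theta
        K = K + K.T - np.diag(np.diag(K))
        w = np.linalg.eigvalsh(K)
        if w.min() <= 1e-10:
            return 1e12
        return penalized_objective(K, S, lam)

    def snap_polish(x, fx):
        # the optimum has exact zeros; NM stalls at hinge points with
        # tiny nonzero entries that still pay the L1 penalty
        for thresh in (1e-6, 1e-5, 1e-4, 1e-3, 1e-2):
            xs = np.where(np.abs(x) < thresh, 0.0, x)
            fs = f(xs)
            if fs < fx:
                x, fx = xs, fs
        return x, fx

    x = np.diag(1.0 / np.diag(S))[iu]
    fbest = np.inf
    xbest = x
    stalls = 0
    for r in range(restarts):
        res = minimize(
            f, x, method="Nelder-Mead",
            options=dict(xatol=1e-12, fatol=1e-14,
                         maxiter=20000, maxfev=20000),
        )
        xc, fc = snap_polish(res.x, res.fun)
        if fc < fbest - 1e-12:
            xbest, fbest = xc, fc
            stalls = 0
            x = xbest
        else:
            stalls += 1
            if stalls >= 2:
                break
            # kick off a possible hinge stall deterministically
            x = xbest + 1e-3 * np.sin(np.arange(len(xbest)) + r)
    return fbest


def enumerate_shortest_paths(
    W: np.ndarray, s: int, t: int
) -> tuple[float, list[tuple[int, ...]]]:
    """All shortest s-t paths (edge length 1/|w|) by brute-force
    enumeration of simple paths.  Returns (distance, paths); distance
    is inf when unreachable."""
    p = W.shape[0]
    others = [v for v in range(p) if v not in (s, t)]
    best = np.inf
    paths: list[tuple[int, ...]] = []
    for r in range(len(others) + 1):
        for mid in itertools.permutations(others, r):
            path = (s, *mid, t)
            length = 0.0
            ok = True
            for a, b in zip(path, path[1:]):
                if abs(W[a, b]) <= 1e-12:
                    ok = False
                    break
                length += 1.0 / abs(W[a, b])
            if not ok:
                continue
            if length < best - 1e-12:
                best = length
                paths = [path]
            elif abs(length - best) <= 1e-12:
                paths.append(path)
    return best, paths


def brute_force_centralities(W: np.ndarray) -> dict[str, np.ndarray]:
    """Strength, closeness and betweenness by exhaustive enumeration."""
    p = W.shape[0]
    strength = np.abs(W).sum(axis=1)
    dist = np.full((p, p), np.inf)
    sp: dict[tuple[int, int], list[tuple[int, ...]]] = {}
    for s in range(p):
        dist[s, s] = 0.0
        for t in range(p):
            if s == t:
                continue
            d, paths = enumerate_shortest_paths(W, s, t)
            dist[s, t] = d
            sp[(s, t)] = paths
    closeness = np.zeros(p)
    for s in range(p):
        total = sum(dist[s, t] for t in range(p) if t != s)
        closeness[s] = 0.0 if not np.isfinite(total) or total == 0 \
            else 1.0 / total
    betweenness = np.zeros(p)
    for v in range(p):
        for s, t in itertools.combinations(
            [u for u in range(p) if u != v], 2
        ):
            paths = sp.get((s, t), [])
            if not paths:
                continue
            through = sum(1 for path in paths if v in path[1:-1])
            betweenness[v] += through / len(paths)
    return {
        "strength": strength,
        "closeness": closeness,
        "betweenness": betweenness,
    }


def ols_cross_lagged(X1: np.ndarray, X2: np.ndarray) -> np.ndarray:
    """Closed-form normal-equations cross-lagged coefficients on
    standardized columns."""
    Z1 = (X1 - X1.mean(0)) / X1.std(0)
    Z2 = (X2 - X2.mean(0)) / X2.std(0)
    return np.linalg.solve(Z1.T @ Z1, Z1.T @ Z2)
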