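"""Regularized partial-correlation networks with EBIC model selection.

A Gaussian graphical model treats the seven construct scores as jointly
normal; zeros in the precision (inverse covariance) matrix encode
conditional independence, and the off-diagonal entries map to partial
correlations ``rho_ij = -K_ij / sqrt(K_ii K_jj)``.  The network is
estimated by fitting the graphical lasso along a logarithmically spaced
penalty path (100 models by default, from the fully shrunk empty graph
down to 1% of that penalty) and selecting the model minimizing the
extended Bayesian information criterion

    EBIC = -2 loglik + E ln(n) + 4 gamma E ln(p)

with hyperparameter ``gamma = 0.5``, where E is the number of nonzero
edges.  The log-likelihood is that of the penalized estimate itself
(no unpenalized refit).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .glasso import glasso_path

#: Off-diagonal weights at or below this magnitude count as exact zeros.
EDGE_EPS = 1e-8


@dataclass
class WeightedNetwork:
    """Undirected signed weighted network of partial correlations."""

    labels: list[str]
    W: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        p = len(self.labels)
        if self.W.shape != (p, p):
            raise ValueError("weight matrix does not match labels")
        if not np.allclose(self.W, self.W.T, atol=1e-8):
            raise ValueError("weight matrix must be symmetric")
        if np.any(np.abs(np.diag(self.W)) > 1e-12):
            raise ValueError("diagonal must be zero")
        if np.any(np.abs(self.W) >= 1.0):
            raise ValueError("partial correlations must satisfy |w| < 1")
        self.W = 0.5 * (self.W + self.W.T)
        np.fill_diagonal(self.W, 0.0)

    @property
    def p(self) -> int:
        return len(self.labels)

    @property
    def n_possible_edges(self) -> int:
        return self.p * (self.p - 1) // 2

    @property
    def n_edges(self) -> int:
        iu = np.triu_indices(self.p, 1)
        return int(np.sum(np.abs(self.W[iu]) > EDGE_EPS))

    @property
    def density(self) -> float:
        """Fraction of possible node pairs with a nonzero edge.

        Some applied reports label this quantity "sparsity"; it is the
        edge density (19 of 21 edges -> 0.905).
        """
        return self.n_edges / self.n_possible_edges

    def edge_list(self) -> pd.DataFrame:
        """Nonzero edges as rows (node_a, node_b, weight), upper
        triangle order."""
        rows = []
        for i in range(self.p):
            for j in range(i + 1, self.p):
                w = self.W[i, j]
                if abs(w) > EDGE_EPS:
                    rows.append(
                        {"node_a": self.labels[i],
                         "node_b": self.labels[j],
                         "weight": w}
                    )
        return pd.DataFrame(rows, columns=["node_a", "node_b", "weight"])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.W, index=self.labels, columns=self.labels)

    def save(self, stem: str | Path) -> None:
        """Write matrix CSV, edge-list TSV and meta JSON next to
        ``stem``."""
        stem = Path(stem)
        self.to_frame().to_csv(stem.with_suffix(".matrix.csv"))
        self.edge_list().to_csv(
            stem.with_suffix(".edges.tsv"), sep="\t", index=False
        )
        meta = dict(self.meta)
        meta["labels"] = self.labels
        meta["density"] = self.density
        meta["n_edges"] = self.n_edges
        stem.with_suffix(".meta.json").write_text(
            json.dumps(meta, indent=2, sort_keys=True)
        )


def correlation_matrix(scores: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Pearson correlation matrix of a complete score table (n x p)."""
    X = np.asarray(scores, dtype=float)
    n, p = X.shape
    if n < p + 1:
        raise ValueError(f"need at least p+1={p + 1} rows, got {n}")
    if np.any(~np.isfinite(X)):
        raise ValueError("scores contain missing or non-finite values")
    sd = X.std(axis=0)
    if np.any(sd == 0):
        bad = [i for i, s in enumerate(sd) if s == 0]
        raise ValueError(f"zero-variance columns at positions {bad}")
    S = np.corrcoef(X, rowvar=False)
    return 0.5 * (S + S.T)


def precision_to_partial(K: np.ndarray) -> np.ndarray:
    """Partial correlations from a precision matrix; zero diagonal."""
    K = np.asarray(K, dtype=float)
    d = np.sqrt(np.diag(K))
    P = -K / np.outer(d, d)
    P = 0.5 * (P + P.T)
    np.fill_diagonal(P, 0.0)
    return P


def ebic(
    loglik: float, n_edges: int, n: int, p: int, gamma: float = 0.5
) -> float:
    """Extended BIC; ``gamma = 0`` reduces to the ordinary BIC."""
    return float(
        -2.0 * loglik
        + n_edges * np.log(n)
        + 4.0 * gamma * n_edges * np.log(p)
    )


def lambda_path(
    S: np.ndarray, path_size: int = 100, min_ratio: float = 0.01
) -> np.ndarray:
    """Log-spaced decreasing penalty path from the empty-graph penalty
    ``lam_max = max off-diagonal |S|`` down to ``lam_max * min_ratio``."""
    off = np.abs(S - np.diag(np.diag(S)))
    lam_max = float(off.max())
    if lam_max <= 0:
        lam_max = 1e-4
    if path_size == 1:
        return np.array([lam_max])
    return np.exp(
        np.linspace(np.log(lam_max), np.log(lam_max * min_ratio), path_size)
    )


def _gaussian_loglik(K: np.ndarray, S: np.ndarray, n: int) -> float:
    sign, logdet = np.linalg.slogdet(K)
    return 0.5 * n * (logdet - np.trace(S @ K))


@dataclass(frozen=True)
class EstimatorConfig:
    """Hyperparameters of the EBIC-glasso network estimator.

    Resampling procedures re-estimate thousands of networks; a shorter
    penalty path (``path_size``) trades a coarser model search for
    speed without changing the estimator's definition.
    """

    gamma: float = 0.5
    path_size: int = 100
    min_ratio: float = 0.01
    tol: float = 1e-6


def fit_weights(
    X: np.ndarray, config: EstimatorConfig = EstimatorConfig()
) -> tuple[np.ndarray, dict]:
    """Lean core of :func:`estimate_network`: data matrix in,
    partial-correlation weight matrix and selection metadata out."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    S = correlation_matrix(X)
    if not np.all(np.isfinite(S)):
        raise ValueError("degenerate correlation matrix")
    lams = lambda_path(S, config.path_size, config.min_ratio)
    Ks = glasso_path(S, lams, tol=config.tol)
    iu = np.triu_indices(p, 1)
    best = None
    for i in range(len(lams)):
        K = Ks[i]
        E = int(np.sum(np.abs(K[iu]) > EDGE_EPS))
        crit = ebic(_gaussian_loglik(K, S, n), E, n, p, config.gamma)
        if best is None or crit < best[0]:
            best = (crit, i)
    crit, idx = best
    W = precision_to_partial(Ks[idx])
    W[np.abs(W) <= EDGE_EPS] = 0.0
    meta = {
        "lambda_selected": float(lams[idx]),
        "gamma": config.gamma,
        "ebic_value": float(crit),
        "n": int(n),
        "path_size": int(config.path_size),
    }
    return W, meta


def estimate_network(
    scores: pd.DataFrame,
    gamma: float = 0.5,
    path_size: int = 100,
    min_ratio: float = 0.01,
    tol: float = 1e-6,
) -> WeightedNetwork:
    """Estimate the EBIC-selected regularized partial-correlation
    network from one wave's construct scores.

    Deterministic: the same table and hyperparameters always yield the
    same network.
    """
    labels = (
        list(scores.columns)
        if isinstance(scores, pd.DataFrame)
        else [f"V{i + 1}" for i in range(np.asarray(scores).shape[1])]
    )
    config = EstimatorConfig(
        gamma=gamma, path_size=path_size, min_ratio=min_ratio, tol=tol
    )
    W, meta = fit_weights(np.asarray(scores, dtype=float), config)
    return WeightedNetwork(labels=labels, W=W, meta=meta)
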