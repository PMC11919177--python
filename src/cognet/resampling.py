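"""Bootstrap accuracy and stability diagnostics for estimated networks.

Two procedures, both re-running the full EBIC-glasso estimator on each
replicate:

* **Edge-weight accuracy** — nonparametric bootstrap: resample
  respondents with replacement, re-estimate the network, and report
  percentile 95% confidence intervals per edge.
* **Centrality stability** — case-drop bootstrap: for each drop
  proportion in a grid (5%..75% in 5% steps), repeatedly subsample the
  remaining cases without replacement, re-estimate, and correlate the
  subsample centralities with the full-sample ones.  The
  correlation-stability (CS) coefficient is the largest drop proportion
  at which the correlation stays at or above 0.7 in at least 95% of
  subsamples (and at every smaller proportion); 0 if none.  CS above
  0.5 is conventionally read as stable, below 0.25 as unstable.  With a
  0.05-step grid capped at 0.75, a perfectly stable index reports the
  grid ceiling 0.75.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import centrality as centrality_mod
from .ggm import EstimatorConfig, WeightedNetwork, fit_weights

DEFAULT_DROP_GRID = tuple(np.round(np.arange(0.05, 0.76, 0.05), 2))

_CENTRALITY_FNS = {
    "strength": centrality_mod.strength,
    "closeness": centrality_mod.closeness,
    "betweenness": centrality_mod.betweenness,
}


@dataclass
class BootstrapResult:
    """Holds edge CIs and/or case-drop stability output."""

    B: int
    seed: int
    edge_ci: pd.DataFrame | None = None
    n_failed: int = 0
    cs: dict[str, float] = field(default_factory=dict)
    curves: pd.DataFrame | None = None
    drop_grid: tuple[float, ...] = ()
    cor_threshold: float = 0.7
    prob_threshold: float = 0.95

    def summary(self) -> dict:
        out: dict = {"B": self.B, "seed": self.seed,
                     "n_failed": self.n_failed}
        if self.cs:
            out["cs"] = dict(self.cs)
            out["drop_grid"] = list(self.drop_grid)
            out["cor_threshold"] = self.cor_threshold
            out["prob_threshold"] = self.prob_threshold
        if self.edge_ci is not None:
            out["n_edges_ci"] = int(len(self.edge_ci))
        return out


def bootstrap_edges(
    scores: pd.DataFrame,
    config: EstimatorConfig = EstimatorConfig(),
    B: int = 1000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> BootstrapResult:
    """Percentile bootstrap confidence intervals for every possible
    edge weight (zero-weight pairs included, so CIs containing 0 are
    visible)."""
    if B < 100:
        raise ValueError("B must be >= 100 for percentile intervals")
    X = np.asarray(scores, dtype=float)
    labels = list(scores.columns)
    n, p = X.shape
    rng = np.random.default_rng(seed)
    W0, _ = fit_weights(X, config)
    iu = np.triu_indices(p, 1)
    draws = np.empty((B, len(iu[0])))
    n_failed = 0
    kept = 0
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        try:
            Wb, _ = fit_weights(X[idx], config)
        except (ValueError, np.linalg.LinAlgError, RuntimeError):
            n_failed += 1
            continue
        draws[kept] = Wb[iu]
        kept += 1
    if kept == 0:
        raise RuntimeError("all bootstrap replicates failed")
    draws = draws[:kept]
    alpha = 1.0 - ci_level
    lower = np.quantile(draws, alpha / 2, axis=0)
    upper = np.quantile(draws, 1 - alpha / 2, axis=0)
    edge_ci = pd.DataFrame({
        "node_a": [labels[i] for i in iu[0]],
        "node_b": [labels[j] for j in iu[1]],
        "point": W0[iu],
        "lower": lower,
        "upper": upper,
    })
    return BootstrapResult(
        B=B, seed=seed, edge_ci=edge_ci, n_failed=n_failed
    )


def _centrality_vector(
    W: np.ndarray, labels: list[str], which: str
) -> np.ndarray:
    net = WeightedNetwork(labels=labels, W=W)
    return _CENTRALITY_FNS[which](net).to_numpy()


def case_drop_cs(
    scores: pd.DataFrame,
    config: EstimatorConfig = EstimatorConfig(),
    centrality: str = "strength",
    drop_grid: tuple[float, ...] = DEFAULT_DROP_GRID,
    B: int = 250,
    seed: int = 0,
    cor_threshold: float = 0.7,
    prob_threshold: float = 0.95,
    cor_method: str = "spearman",
) -> BootstrapResult:
    """Case-drop bootstrap of one centrality index -> CS coefficient.

    Subsamples whose centrality vector is constant (correlation
    undefined) count as failures at that level.  Levels whose subsample
    would have fewer than p+1 cases are skipped with a warning entry in
    the curve table.
    """
    if centrality not in _CENTRALITY_FNS:
        raise ValueError(f"unknown centrality {centrality!r}")
    X = np.asarray(scores, dtype=float)
    labels = list(scores.columns)
    n, p = X.shape
    rng = np.random.default_rng(seed)
    W0, _ = fit_weights(X, config)
    c_full = _centrality_vector(W0, labels, centrality)

    def correlate(a: np.ndarray, b: np.ndarray) -> float:
        if np.std(a) == 0 or np.std(b) == 0:
            return np.nan
        if cor_method == "spearman":
            return float(stats.spearmanr(a, b).statistic)
        return float(np.corrcoef(a, b)[0, 1])

    rows = []
    for drop in drop_grid:
        m = int(round((1.0 - drop) * n))
        if m < p + 1:
            rows.append({"drop": drop, "prop_ok": np.nan,
                         "mean_cor": np.nan, "skipped": True})
            continue
        cors = np.empty(B)
        for b in range(B):
            idx = rng.choice(n, size=m, replace=False)
            try:
                Wb, _ = fit_weights(X[idx], config)
                cors[b] = correlate(
                    _centrality_vector(Wb, labels, centrality), c_full
                )
            except (ValueError, np.linalg.LinAlgError, RuntimeError):
                cors[b] = np.nan
        ok = np.mean(np.nan_to_num(cors, nan=-np.inf) >= cor_threshold)
        rows.append({
            "drop": drop,
            "prop_ok": float(ok),
            "mean_cor": float(np.nanmean(cors)) if np.any(
                np.isfinite(cors)) else np.nan,
            "skipped": False,
        })
    curves = pd.DataFrame(rows)
    cs = 0.0
    for row in curves.itertuples():
        if row.skipped or not (row.prop_ok >= prob_threshold):
            break
        cs = float(row.drop)
    return BootstrapResult(
        B=B, seed=seed, cs={centrality: cs}, curves=curves,
        drop_grid=tuple(drop_grid), cor_threshold=cor_threshold,
        prob_threshold=prob_threshold,
    )
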