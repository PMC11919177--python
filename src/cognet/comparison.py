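"""Permutation comparison of two estimated networks.

Tests two kinds of invariance between groups (or waves):

* **global strength** — the summed absolute edge weights of each
  network; the statistic is the absolute difference;
* **edge weights** — an omnibus maximum absolute edge difference, plus
  per-edge differences with multiplicity-adjusted p values (Holm by
  default).

The null distribution is built by re-estimating both networks after
permuting group membership: full label permutation for independent
groups, or per-subject wave swapping (each subject's two rows exchanged
with probability 1/2) for paired two-wave data, which respects the
within-subject dependence.  p values use the add-one permutation
estimator ``(1 + #{null >= observed}) / (1 + n_perm)`` and therefore
never equal zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .ggm import EstimatorConfig, WeightedNetwork, fit_weights


def global_strength(net: WeightedNetwork | np.ndarray) -> float:
    """Sum of absolute edge weights over unordered node pairs."""
    W = net.W if isinstance(net, WeightedNetwork) else np.asarray(net)
    iu = np.triu_indices(W.shape[0], 1)
    return float(np.abs(W[iu]).sum())


@dataclass
class NCTResult:
    """Outcome of the permutation network-comparison test."""

    gs1: float
    gs2: float
    gs_diff: float
    gs_p: float
    omnibus_stat: float
    omnibus_p: float
    edges: pd.DataFrame
    n_perm: int
    seed: int
    design: str
    adjust: str
    net1: WeightedNetwork | None = None
    net2: WeightedNetwork | None = None

    def to_dict(self) -> dict:
        return {
            "gs1": self.gs1, "gs2": self.gs2,
            "gs_diff": self.gs_diff, "gs_p": self.gs_p,
            "omnibus_stat": self.omnibus_stat,
            "omnibus_p": self.omnibus_p,
            "n_perm": self.n_perm, "seed": self.seed,
            "design": self.design, "adjust": self.adjust,
        }

    def save(self, stem: str | Path) -> None:
        stem = Path(stem)
        stem.with_suffix(".json").write_text(
            json.dumps(self.to_dict(), indent=2, sort_keys=True)
        )
        self.edges.to_csv(stem.with_suffix(".edges.csv"), index=False)


def _adjust(pvals: np.ndarray, method: str) -> np.ndarray:
    if method == "none":
        return pvals
    name = {"holm": "holm", "bonferroni": "bonferroni", "bh": "fdr_bh"}
    if method not in name:
        raise ValueError(f"unknown adjustment {method!r}")
    return multipletests(pvals, method=name[method])[1]


def nct(
    scores_a: pd.DataFrame,
    scores_b: pd.DataFrame,
    design: str = "independent",
    n_perm: int = 1000,
    seed: int = 0,
    config: EstimatorConfig = EstimatorConfig(),
    adjust: str = "holm",
    keep_networks: bool = True,
) -> NCTResult:
    """Permutation network-comparison test between two score tables.

    For the paired design the two tables must hold the same subjects in
    the same row order.
    """
    if list(scores_a.columns) != list(scores_b.columns):
        raise ValueError("node sets (columns) differ between groups")
    if design not in ("independent", "paired"):
        raise ValueError("design must be 'independent' or 'paired'")
    labels = list(scores_a.columns)
    A = np.asarray(scores_a, dtype=float)
    Bm = np.asarray(scores_b, dtype=float)
    if design == "paired" and len(A) != len(Bm):
        raise ValueError("paired design needs equal group sizes")
    p = len(labels)
    iu = np.triu_indices(p, 1)

    Wa, meta_a = fit_weights(A, config)
    Wb, meta_b = fit_weights(Bm, config)
    gs1, gs2 = global_strength(Wa), global_strength(Wb)
    obs_gs = abs(gs1 - gs2)
    obs_edge = np.abs(Wa[iu] - Wb[iu])
    obs_omni = float(obs_edge.max()) if len(obs_edge) else 0.0

    rng = np.random.default_rng(seed)
    n_a = len(A)
    pooled = np.vstack([A, Bm])
    ge_gs = 0
    ge_omni = 0
    ge_edge = np.zeros(len(obs_edge), dtype=int)
    for _ in range(n_perm):
        if design == "independent":
            perm = rng.permutation(len(pooled))
            Xa, Xb = pooled[perm[:n_a]], pooled[perm[n_a:]]
        else:
            swap = rng.random(n_a) < 0.5
            Xa, Xb = A.copy(), Bm.copy()
            Xa[swap], Xb[swap] = Bm[swap], A[swap]
        Wpa, _ = fit_weights(Xa, config)
        Wpb, _ = fit_weights(Xb, config)
        gs_null = abs(global_strength(Wpa) - global_strength(Wpb))
        edge_null = np.abs(Wpa[iu] - Wpb[iu])
        if gs_null >= obs_gs:
            ge_gs += 1
        if len(edge_null) and edge_null.max() >= obs_omni:
            ge_omni += 1
        ge_edge += edge_null >= obs_edge
    denom = 1.0 + n_perm
    gs_p = (1.0 + ge_gs) / denom
    omni_p = (1.0 + ge_omni) / denom
    edge_p = (1.0 + ge_edge) / denom
    edges = pd.DataFrame({
        "node_a": [labels[i] for i in iu[0]],
        "node_b": [labels[j] for j in iu[1]],
        "w1": Wa[iu],
        "w2": Wb[iu],
        "diff": Wa[iu] - Wb[iu],
        "abs_diff": obs_edge,
        "p": edge_p,
        "p_adjusted": _adjust(edge_p, adjust),
    })
    return NCTResult(
        gs1=gs1, gs2=gs2, gs_diff=obs_gs, gs_p=gs_p,
        omnibus_stat=obs_omni, omnibus_p=omni_p, edges=edges,
        n_perm=n_perm, seed=seed, design=design, adjust=adjust,
        net1=WeightedNetwork(labels, Wa, meta_a) if keep_networks else None,
        net2=WeightedNetwork(labels, Wb, meta_b) if keep_networks else None,
    )
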