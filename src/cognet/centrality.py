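"""Node centrality for weighted psychometric networks.

For undirected partial-correlation networks three indices are used:

* **strength** — sum of absolute edge weights at a node;
* **closeness** — reciprocal of the summed shortest-path distances to
  all other nodes, with edge length ``1 / |w|`` (so stronger edges are
  shorter; higher closeness = more central);
* **betweenness** — number of shortest paths between other node pairs
  passing through the node (fractional credit for ties, Brandes
  convention), same distances.

Signed weights enter the distances and strength by absolute value.
For directed cross-lagged networks the signed expected-influence
measures are used instead: incoming EI (column sums of the coefficient
matrix) and outgoing EI (row sums), normally excluding the
autoregressive diagonal.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd

from .ggm import EDGE_EPS, WeightedNetwork


def _as_graph(net: WeightedNetwork) -> nx.Graph:
    G = nx.Graph()
    G.add_nodes_from(range(net.p))
    for i in range(net.p):
        for j in range(i + 1, net.p):
            w = net.W[i, j]
            if abs(w) > EDGE_EPS:
                G.add_edge(i, j, distance=1.0 / abs(w))
    return G


def strength(net: WeightedNetwork) -> pd.Series:
    """Absolute-weight degree of each node."""
    vals = np.abs(net.W).sum(axis=1)
    return pd.Series(vals, index=net.labels, name="strength")


def closeness(net: WeightedNetwork) -> pd.Series:
    """Reciprocal of total shortest-path distance; 0 for nodes that
    cannot reach every other node."""
    G = _as_graph(net)
    out = np.zeros(net.p)
    lengths = dict(
        nx.all_pairs_dijkstra_path_length(G, weight="distance")
    )
    for i in range(net.p):
        d = lengths.get(i, {})
        if len(d) < net.p:  # some node unreachable
            out[i] = 0.0
        else:
            total = sum(v for k, v in d.items() if k != i)
            out[i] = 1.0 / total if total > 0 else 0.0
    return pd.Series(out, index=net.labels, name="closeness")


def betweenness(net: WeightedNetwork) -> pd.Series:
    """Shortest-path throughput per node (unnormalized, fractional for
    tied shortest paths), counted over unordered pairs."""
    G = _as_graph(net)
    bc = nx.betweenness_centrality(G, weight="distance", normalized=False)
    return pd.Series(
        [bc[i] for i in range(net.p)], index=net.labels, name="betweenness"
    )


def zscore(table: pd.DataFrame) -> pd.DataFrame:
    """Standardize each column across nodes (population denominator).

    Constant columns come back as zeros and are listed in
    ``result.attrs['degenerate_columns']``.
    """
    out = {}
    degenerate = []
    for col in table.columns:
        x = table[col].to_numpy(float)
        sd = x.std()
        if sd == 0:
            out[f"z_{col}"] = np.zeros_like(x)
            degenerate.append(col)
        else:
            out[f"z_{col}"] = (x - x.mean()) / sd
    z = pd.DataFrame(out, index=table.index)
    z.attrs["degenerate_columns"] = degenerate
    return z


def centrality_table(net: WeightedNetwork) -> pd.DataFrame:
    """Strength, closeness and betweenness, raw and z-scored."""
    raw = pd.concat(
        [strength(net), closeness(net), betweenness(net)], axis=1
    )
    z = zscore(raw)
    table = pd.concat([raw, z], axis=1)
    table.attrs["degenerate_columns"] = z.attrs["degenerate_columns"]
    table.index.name = "node"
    return table


def expected_influence(
    B: np.ndarray,
    labels: list[str],
    mode: str,
    exclude_self: bool = True,
) -> pd.Series:
    """Signed expected influence of each node in a directed network.

    ``mode='in'`` sums a node's incoming coefficients (how much the
    wave-1 system predicts it); ``mode='out'`` sums its outgoing ones
    (how much it predicts the wave-2 system).  The autoregressive
    diagonal is excluded by default.
    """
    B = np.asarray(B, dtype=float)
    M = B.copy()
    if exclude_self:
        np.fill_diagonal(M, 0.0)
    if mode == "in":
        vals = M.sum(axis=0)
    elif mode == "out":
        vals = M.sum(axis=1)
    else:
        raise ValueError("mode must be 'in' or 'out'")
    return pd.Series(vals, index=labels, name=f"{mode}_ei")
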