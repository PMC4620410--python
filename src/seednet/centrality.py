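"""Per-node network metrics and the degree-distribution diagnostic.

Seven metrics are computed on the (connected) giant component of the
seed subnetwork, all on unweighted shortest paths:

========================  =====================================================
degree                    k_v, number of interaction partners
betweenness               Brandes betweenness, endpoints excluded, normalized
                          by (n-1)(n-2)/2 — fraction of shortest paths through v
closeness                 c(v) = 1 / sum_w d(v, w)  (literal reciprocal-of-sum
                          form; differs from the (n-1)/sum convention only by a
                          constant factor on a fixed graph, so rankings agree)
radiality                 rad(v) = sum_w (delta_G + 1 - d(v, w)) / (n - 1),
                          delta_G the graph diameter (Valente–Foreman form)
clustering                C(v) = 2 e_N / (k_v (k_v - 1)), e_N edges among
                          neighbors of v; 0 when k_v < 2
topological               T(v) = mean_w J(v, w) / k_v over nodes w != v sharing
                          at least one neighbor with v; J(v, w) = number of
                          shared neighbors, plus 1 if v and w are adjacent
neigh_conn                mean degree of the neighbors of v
========================  =====================================================

The power-law fit is a log–log least-squares diagnostic on the degree
CCDF — adequate for a scale-freeness eyeball check, not a rigorous
maximum-likelihood estimator.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .exceptions import DisconnectedGraphError, ValidationError

METRIC_COLUMNS = (
    "degree", "betweenness", "closeness", "radiality",
    "clustering", "topological", "neigh_conn",
)


def _require_connected(g: nx.Graph) -> None:
    if g.number_of_nodes() == 0 or not nx.is_connected(g):
        raise DisconnectedGraphError(
            "graph is empty or disconnected; path-based metrics need a "
            "connected graph — extract the giant component first"
        )


def all_pairs_distances(g: nx.Graph) -> dict[str, dict[str, int]]:
    """All-pairs shortest-path hop counts by BFS from every node."""
    _require_connected(g)
    return {v: dict(nx.single_source_shortest_path_length(g, v)) for v in g}


def diameter(dist: Mapping[str, Mapping[str, int]]) -> int:
    return max((d for row in dist.values() for d in row.values()), default=0)


def degree(g: nx.Graph) -> dict[str, int]:
    return {v: d for v, d in g.degree()}


def betweenness(g: nx.Graph) -> dict[str, float]:
    """Normalized Brandes betweenness; all zeros when n < 3."""
    _require_connected(g)
    if g.number_of_nodes() < 3:
        return {v: 0.0 for v in g}
    return nx.betweenness_centrality(g, normalized=True, endpoints=False)


def closeness(g: nx.Graph,
              dist: Mapping[str, Mapping[str, int]] | None = None) -> dict[str, float]:
    """Reciprocal of the summed shortest-path distances from each node."""
    if dist is None:
        dist = all_pairs_distances(g)
    if len(dist) < 2:
        raise ValidationError("closeness needs at least 2 nodes")
    return {v: 1.0 / sum(d for w, d in row.items() if w != v)
            for v, row in dist.items()}


def radiality(g: nx.Graph,
              dist: Mapping[str, Mapping[str, int]] | None = None) -> dict[str, float]:
    """Diameter-referenced closeness variant; larger for more central nodes."""
    if dist is None:
        dist = all_pairs_distances(g)
    if len(dist) < 2:
        raise ValidationError("radiality needs at least 2 nodes")
    delta = diameter(dist)
    n = len(dist)
    return {
        v: sum(delta + 1 - d for w, d in row.items() if w != v) / (n - 1)
        for v, row in dist.items()
    }


def clustering_coefficient(g: nx.Graph) -> dict[str, float]:
    return {v: float(c) for v, c in nx.clustering(g).items()}


def topological_coefficient(g: nx.Graph) -> dict[str, float]:
    """Shared-neighbor statistic of Stelzl et al.; low for hubs."""
    adj = {v: set(g[v]) for v in g}
    out: dict[str, float] = {}
    for v in g:
        kv = len(adj[v])
        if kv == 0:
            out[v] = 0.0
            continue
        partners = set()
        for u in adj[v]:
            partners.update(adj[u])
        partners.discard(v)
        total = 0.0
        count = 0
        for w in partners:
            shared = len(adj[v] & adj[w])
            if shared == 0:
                continue
            total += shared + (1 if w in adj[v] else 0)
            count += 1
        out[v] = (total / count) / kv if count else 0.0
    return out


def neighborhood_connectivity(g: nx.Graph) -> dict[str, float]:
    nc = nx.average_neighbor_degree(g)
    return {v: float(nc.get(v, 0.0)) if g.degree(v) > 0 else 0.0 for v in g}


def compute_centrality_table(g: nx.Graph) -> pd.DataFrame:
    """Compute all seven metrics on a connected graph.

    Returns a DataFrame indexed by node with one column per metric
    (see ``METRIC_COLUMNS``); the graph diameter and node count are
    stashed in ``DataFrame.attrs``.
    """
    _require_connected(g)
    dist = all_pairs_distances(g)
    data = {
        "degree": degree(g),
        "betweenness": betweenness(g),
        "closeness": closeness(g, dist),
        "radiality": radiality(g, dist),
        "clustering": clustering_coefficient(g),
        "topological": topological_coefficient(g),
        "neigh_conn": neighborhood_connectivity(g),
    }
    table = pd.DataFrame(data, columns=list(METRIC_COLUMNS))
    table = table.sort_index()
    table.index.name = "node"
    table.attrs["diameter"] = diameter(dist)
    table.attrs["n_nodes"] = g.number_of_nodes()
    return table


def fit_power_law(degrees: Sequence[int]) -> tuple[float, float]:
    """Least-squares power-law diagnostic on the degree distribution.

    Fits a line to log10(CCDF) versus log10(degree) over the unique
    positive degree values and returns ``(exponent, r_squared)`` where
    the exponent is the slope magnitude. For a pure power law
    p(k) ~ k**-gamma the CCDF slope magnitude is gamma - 1.
    """
    deg = np.asarray(degrees, dtype=float)
    deg = deg[deg >= 1]
    if deg.size < 20:
        raise ValidationError(
            f"power-law fit needs >= 20 nodes with degree >= 1, got {deg.size}")
    uniq = np.unique(deg)
    if uniq.size < 2:
        raise ValidationError("power-law fit needs spread in the degrees")
    ccdf = np.array([(deg >= k).mean() for k in uniq])
    x = np.log10(uniq)
    y = np.log10(ccdf)
    slope, intercept = np.polyfit(x, y, 1)
    ss_res = float(np.sum((y - (slope * x + intercept)) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return float(abs(slope)), float(r2)
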