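"""Node-level graph attributes for single-layer and multilayer networks.

For a binary undirected network with N nodes the per-node attributes are

* degree ``d_i``: number of incident edges;
* clustering ``C_i``: closed triangles at i over ``d_i (d_i - 1) / 2``
  possible neighbor pairs (0 when ``d_i < 2``);
* local efficiency ``E_i``: mean over ordered neighbor pairs of the
  inverse shortest-path length computed *within* the subgraph induced by
  i's neighbors (disconnected pairs contribute 0; 0 when ``d_i < 2``);
* connectivity robustness ``R_i``: after deleting node i, the mean
  degree of the surviving N-1 nodes divided by N-1.

Multilayer attributes are node-wise sums of the single-layer values
across band layers — unweighted for the plain multilayer network, or
weighted by each layer's power-spectral ratio ``∂`` for the improved
multilayer network (the ∂ sum to 1 per sample, so the improved variant
is a convex combination of the layers).

The fast path uses networkx; :func:`metric_oracle` recomputes everything
by naive enumeration (triangle loops, Floyd-Warshall, explicit node
deletion) and exists purely as an independent cross-check in tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .connectivity import BinaryNetwork

METRIC_NAMES = ("degree", "clustering", "local_efficiency", "robustness")


@dataclass
class NodeMetricSet:
    """Per-node attribute vectors for one network."""

    nodes: tuple[str, ...]
    degree: np.ndarray
    clustering: np.ndarray
    local_efficiency: np.ndarray
    robustness: np.ndarray
    provenance: str = ""

    def as_dict(self) -> dict[str, np.ndarray]:
        return {
            "degree": self.degree,
            "clustering": self.clustering,
            "local_efficiency": self.local_efficiency,
            "robustness": self.robustness,
        }


@dataclass
class MultilayerMetricSet:
    """Layer-aggregated per-node attributes with the weights used."""

    nodes: tuple[str, ...]
    degree: np.ndarray
    clustering: np.ndarray
    local_efficiency: np.ndarray
    robustness: np.ndarray
    layers: tuple[str, ...]
    weights: np.ndarray
    provenance: str = ""

    def as_dict(self) -> dict[str, np.ndarray]:
        return {
            "degree": self.degree,
            "clustering": self.clustering,
            "local_efficiency": self.local_efficiency,
            "robustness": self.robustness,
        }


def degree(net: BinaryNetwork) -> np.ndarray:
    """Row sums of the adjacency matrix."""
    return net.adjacency.sum(axis=1).astype(np.int64)


def clustering(net: BinaryNetwork) -> np.ndarray:
    """Local clustering coefficient per node."""
    g = nx.from_numpy_array(net.adjacency)
    c = nx.clustering(g)
    return np.array([c[i] for i in range(net.n_nodes)], dtype=np.float64)


def local_efficiency(net: BinaryNetwork) -> np.ndarray:
    """Mean inverse shortest-path length within each node's neighbor
    subgraph; 0 for nodes with fewer than 2 neighbors."""
    g = nx.from_numpy_array(net.adjacency)
    out = np.zeros(net.n_nodes)
    for i in range(net.n_nodes):
        nbrs = list(g.neighbors(i))
        if len(nbrs) < 2:
            continue
        out[i] = nx.global_efficiency(g.subgraph(nbrs))
    return out


def robustness(net: BinaryNetwork) -> np.ndarray:
    """R_i = mean degree after deleting node i, over N - 1."""
    n = net.n_nodes
    if n < 2:
        raise ValueError("robustness needs at least 2 nodes")
    a = net.adjacency.astype(np.int64)
    deg = a.sum(axis=1)
    total_deg = deg.sum()
    # deleting node i removes its degree and one unit from each neighbor
    out = np.empty(n)
    for i in range(n):
        remaining = total_deg - 2 * deg[i]
        out[i] = remaining / (n - 1) / (n - 1)
    return out


def node_metrics(net: BinaryNetwork, provenance: str = "") -> NodeMetricSet:
    """All four per-node attributes of one binary network."""
    return NodeMetricSet(
        nodes=tuple(net.node_labels),
        degree=degree(net),
        clustering=clustering(net),
        local_efficiency=local_efficiency(net),
        robustness=robustness(net),
        provenance=provenance or net.band,
    )


def multilayer_metrics(layers: list[NodeMetricSet],
                       weights: np.ndarray | list[float] | None = None,
                       provenance: str = "") -> MultilayerMetricSet:
    """Node-wise (optionally ∂-weighted) sum of metrics across layers."""
    if not layers:
        raise ValueError("need at least one layer")
    nodes = layers[0].nodes
    for lay in layers[1:]:
        if lay.nodes != nodes:
            raise ValueError("layers have mismatched node labels")
    if weights is None:
        w = np.ones(len(layers))
    else:
        w = np.asarray(weights, dtype=np.float64)
        if w.shape != (len(layers),):
            raise ValueError(
                f"expected {len(layers)} weights, got shape {w.shape}"
            )
    agg = {
        name: sum(wi * lay.as_dict()[name] for wi, lay in zip(w, layers))
        for name in METRIC_NAMES
    }
    return MultilayerMetricSet(
        nodes=nodes,
        degree=agg["degree"],
        clustering=agg["clustering"],
        local_efficiency=agg["local_efficiency"],
        robustness=agg["robustness"],
        layers=tuple(lay.provenance for lay in layers),
        weights=w,
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# Brute-force oracle (tests only)
# ---------------------------------------------------------------------------

def _floyd_warshall(a: np.ndarray) -> np.ndarray:
    n = a.shape[0]
    d = np.where(a > 0, 1.0, np.inf)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def metric_oracle(net: BinaryNetwork) -> NodeMetricSet:
    """Naive exhaustive computation of all four metrics (N <= 12 only)."""
    n = net.n_nodes
    if n > 12:
        raise ValueError("oracle is deliberately naive; N <= 12 only")
    a = net.adjacency.astype(np.int64)

    deg = np.array([sum(a[i, j] for j in range(n)) for i in range(n)])

    clust = np.zeros(n)
    for i in range(n):
        if deg[i] < 2:
            continue
        tri = 0
        for j in range(n):
            for k in range(j + 1, n):
                if a[i, j] and a[i, k] and a[j, k]:
                    tri += 1
        clust[i] = tri / (deg[i] * (deg[i] - 1) / 2)

    leff = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if a[i, j]]
        m = len(nbrs)
        if m < 2:
            continue
        sub = a[np.ix_(nbrs, nbrs)]
        d = _floyd_warshall(sub)
        acc = 0.0
        for p in range(m):
            for q in range(m):
                if p != q and np.isfinite(d[p, q]):
                    acc += 1.0 / d[p, q]
        leff[i] = acc / (m * (m - 1))

    rob = np.zeros(n)
    for i in range(n):
        keep = [j for j in range(n) if j != i]
        sub = a[np.ix_(keep, keep)]
        rob[i] = sub.sum(axis=1).mean() / (n - 1)

    return NodeMetricSet(
        nodes=tuple(net.node_labels),
        degree=deg,
        clustering=clust,
        local_efficiency=leff,
        robustness=rob,
        provenance="oracle",
    )
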