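"""Nodal and hemispheric graph-theory metrics.

Implements the metric battery for a single-hemisphere structural
connectome: degree, weighted betweenness centrality (shortest paths on
inverse-weight lengths), weighted clustering coefficient with
geometric-mean triplet intensities on raw streamline weights,
hierarchical complexity of the degree sequence, and its nodal
decomposition (neighbourhood complexity).

Conventions
-----------
* Streamline count is a connection *strength*; shortest paths use the
  length transform ``length = 1 / weight`` (configurable).
* Betweenness sums run over ordered node pairs (h, j).  The *raw*
  variant is that sum; the *normalized* variant divides by
  ``(n - 1)(n - 2)``.
* Clustering: ``c_i = 2 t_i^w / (k_i (k_i - 1))`` with
  ``t_i^w = sum over closed triangles (w_ij w_ih w_jh)^(1/3)`` on raw
  (un-rescaled) weights; nodes of degree < 2 get ``c_i = 0``.
* Hierarchical complexity R and nodal neighbourhood complexity are
  functions of the binary skeleton (integer degrees); weighted input is
  binarized internally.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .adjacency import WeightedAdjacency
from .atlas import NodeAtlas

NODAL_METRICS = ("betweenness", "clustering", "neighbourhood_complexity")
HEMI_METRICS = (
    "betweenness",
    "clustering",
    "hierarchical_complexity",
    "neighbourhood_complexity",
)


def node_degrees(A: WeightedAdjacency) -> np.ndarray:
    """Count of non-zero incident edges per node (weights ignored)."""
    w = A.weights.copy()
    np.fill_diagonal(w, 0.0)
    return (w > 0).sum(axis=1).astype(int)


def to_length_graph(A: WeightedAdjacency, transform: str = "inverse") -> nx.Graph:
    """networkx graph with a ``length`` attribute for shortest paths.

    ``transform='inverse'`` maps weight w > 0 to length 1/w (strength
    semantics); ``'unit'`` gives every edge length 1 (hop counting).
    """
    if transform not in ("inverse", "unit"):
        raise ValueError(f"unknown weight-to-length transform {transform!r}")
    G = nx.Graph()
    G.add_nodes_from(range(A.n))
    i, j = np.nonzero(np.triu(A.weights, k=1))
    for a, b in zip(i.tolist(), j.tolist()):
        w = A.weights[a, b]
        G.add_edge(a, b, weight=w, length=(1.0 / w if transform == "inverse" else 1.0))
    return G


@dataclass(frozen=True)
class ShortestPathTally:
    """Shortest-path counts for one ordered node pair (h, j).

    ``rho``: number of distinct shortest paths from h to j;
    ``via[i]``: how many of them pass through intermediate node i.
    """

    h: int
    j: int
    rho: int
    via: dict


def shortest_path_tallies(
    A: WeightedAdjacency, transform: str = "inverse"
) -> dict:
    """All-pairs shortest-path tallies under the given length transform.

    Enumerates shortest paths explicitly, so intended for small graphs
    (pedagogy and oracle checks); betweenness on full connectomes uses
    Brandes accumulation instead.  Unreachable pairs get ``rho = 0``.
    """
    G = to_length_graph(A, transform)
    out = {}
    for h in range(A.n):
        for j in range(A.n):
            if h == j:
                continue
            via: dict = {}
            rho = 0
            try:
                for path in nx.all_shortest_paths(G, h, j, weight="length"):
                    rho += 1
                    for i in path[1:-1]:
                        via[i] = via.get(i, 0) + 1
            except nx.NetworkXNoPath:
                pass
            out[(h, j)] = ShortestPathTally(h, j, rho, via)
    return out


def betweenness_centrality(
    A: WeightedAdjacency, normalized: bool = False, transform: str = "inverse"
) -> np.ndarray:
    """Per-node betweenness b_i over ordered pairs of other nodes.

    b_i = sum over ordered (h, j), h != j, both != i, of
    rho_hj(i) / rho_hj; divided by (n-1)(n-2) when ``normalized``.
    Unreachable pairs contribute zero.
    """
    if normalized and A.n < 3:
        raise ValueError("normalized betweenness needs n >= 3")
    G = to_length_graph(A, transform)
    # networkx (undirected, normalized=False) counts each unordered pair
    # once; ordered-pair raw sums are twice that.
    bc = nx.betweenness_centrality(G, normalized=False, weight="length")
    raw = 2.0 * np.array([bc[i] for i in range(A.n)])
    if normalized:
        return raw / ((A.n - 1) * (A.n - 2))
    return raw


def clustering_coefficients(
    A: WeightedAdjacency, rescale: bool = False
) -> tuple:
    """Weighted clustering c_i per node and the hemispheric mean C^W.

    c_i = 2 t_i^w / (k_i (k_i - 1)) with geometric-mean triangle
    intensities on raw weights; with ``rescale=True`` weights are first
    divided by the maximum weight (the convention of some toolboxes),
    bounding c_i by 1 on complete triangles.
    """
    w = A.weights.copy()
    np.fill_diagonal(w, 0.0)
    if rescale and w.max() > 0:
        w = w / w.max()
    k = (w > 0).sum(axis=1)
    croot = np.cbrt(w)
    # diag of croot^3 counts each closed triangle at i twice (j,h and h,j)
    t = np.diag(croot @ croot @ croot) / 2.0
    denom = k * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, 2.0 * t / np.where(denom > 0, denom, 1), 0.0)
    return c, float(c.mean())


def _neighbourhood_sequences(A: WeightedAdjacency):
    """Degrees, and per-node ascending neighbour-degree sequences."""
    adj = (A.weights > 0).copy()
    np.fill_diagonal(adj, False)
    k = adj.sum(axis=1).astype(int)
    seqs = [np.sort(k[adj[i]]) for i in range(A.n)]
    return k, seqs


def neighbourhood_complexity(A: WeightedAdjacency) -> tuple:
    """Nodal neighbourhood complexity nc_i and its hemispheric mean.

    For node i of degree p in degree class K_p with |K_p| > 1:
    nc_i = [1 / (p (|K_p| - 1))] * sum_j (s_i^p(j) - mu^p(j))^2, where
    s_i^p is i's ascending neighbour-degree sequence and mu^p the
    entrywise class mean.  Nodes whose degree is unique in the graph
    (or zero) are undefined (NaN) and excluded from the mean.
    """
    k, seqs = _neighbourhood_sequences(A)
    nc = np.full(A.n, np.nan)
    for p in np.unique(k):
        members = np.flatnonzero(k == p)
        if p == 0 or members.size < 2:
            continue
        S = np.vstack([seqs[i] for i in members])  # |K_p| x p
        mu = S.mean(axis=0)
        dev = ((S - mu) ** 2).sum(axis=1)
        nc[members] = dev / (p * (members.size - 1))
    defined = ~np.isnan(nc)
    mean = float(np.mean(nc[defined])) if defined.any() else 0.0
    return nc, mean


def hierarchical_complexity(A: WeightedAdjacency) -> float:
    """Hierarchical complexity R of the (binarized) graph.

    R = (1/D) * sum over degree classes K_p with |K_p| > 1 of
    [1 / (p (|K_p| - 1))] * sum_{j<=p} sum_{i in K_p}
    (s_i^p(j) - mu^p(j))^2, with D the number of distinct degrees in
    the entire network.  Zero for regular graphs.
    """
    k, seqs = _neighbourhood_sequences(A)
    distinct = np.unique(k)
    D = distinct.size
    if D == 0:
        return 0.0
    total = 0.0
    for p in distinct:
        members = np.flatnonzero(k == p)
        if p == 0 or members.size < 2:
            continue
        S = np.vstack([seqs[i] for i in members])
        mu = S.mean(axis=0)
        total += ((S - mu) ** 2).sum() / (p * (members.size - 1))
    return float(total / D)


def nodal_metric_table(
    A: WeightedAdjacency, subject_id: str, transform: str = "inverse"
) -> pd.DataFrame:
    """Tidy per-node metric table for one subject's (thresholded) matrix."""
    k = node_degrees(A)
    b_raw = betweenness_centrality(A, normalized=False, transform=transform)
    b_norm = (
        betweenness_centrality(A, normalized=True, transform=transform)
        if A.n >= 3
        else np.full(A.n, np.nan)
    )
    c, _ = clustering_coefficients(A)
    nc, _ = neighbourhood_complexity(A)
    return pd.DataFrame(
        {
            "subject_id": subject_id,
            "node_label": list(A.labels),
            "degree": k,
            "betweenness_raw": b_raw,
            "betweenness_norm": b_norm,
            "clustering": c,
            "neighbourhood_complexity": nc,
        }
    )


def sensorimotor_slice(table: pd.DataFrame, atlas: NodeAtlas) -> pd.DataFrame:
    """Rows of a nodal metric table restricted to the 8 analysed nodes."""
    wanted = list(atlas.node_labels)
    present = set(table["node_label"])
    missing = [lab for lab in wanted if lab not in present]
    if missing:
        raise KeyError(f"nodes missing from metric table: {missing}")
    out = table[table["node_label"].isin(wanted)].copy()
    out["node_label"] = pd.Categorical(out["node_label"], categories=wanted, ordered=True)
    return out.sort_values(["subject_id", "node_label"]).reset_index(drop=True)


def hemispheric_summary(table: pd.DataFrame, R: float) -> dict:
    """Hemispheric averages of the nodal metrics plus the supplied R.

    ``table`` must be the complete nodal table of one subject; the
    betweenness average uses the raw variant, the neighbourhood-
    complexity average runs over defined nodes only.
    """
    if table["subject_id"].nunique() != 1:
        raise ValueError("hemispheric_summary expects a single subject")
    nc = table["neighbourhood_complexity"].dropna()
    return {
        "betweenness": float(table["betweenness_raw"].mean()),
        "clustering": float(table["clustering"].mean()),
        "hierarchical_complexity": float(R),
        "neighbourhood_complexity": float(nc.mean()) if len(nc) else 0.0,
    }
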