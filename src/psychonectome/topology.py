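"""Topological characterization of a network layer.

Centrality indices (expected influence, strength, degree, weighted
clustering, efficiency), hub identification, extraction of strong simple
paths, and a force-directed layout for plotting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .ggm import ABSENT_TOL, WeightedNetwork

__all__ = [
    "CentralityTable",
    "Path",
    "expected_influence",
    "strength",
    "degree_and_hubs",
    "clustering",
    "efficiency",
    "centrality_table",
    "find_paths",
    "fr_layout",
]


@dataclass
class CentralityTable:
    """Per-node centrality indices for one network layer."""

    node_labels: list[str]
    expected_influence: np.ndarray
    strength: np.ndarray
    degree: np.ndarray
    clustering: np.ndarray
    nodal_efficiency: np.ndarray
    global_efficiency: float
    layer: str = "other"
    meta: dict | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"expected_influence": self.expected_influence,
             "strength": self.strength,
             "degree": self.degree,
             "clustering": self.clustering,
             "nodal_efficiency": self.nodal_efficiency},
            index=self.node_labels)

    def zscored(self) -> pd.DataFrame:
        """Per-index z-scores, the conventional centrality-plot scale."""
        df = self.to_frame().astype(float)
        sd = df.std(ddof=0)
        sd[sd == 0] = 1.0
        return (df - df.mean()) / sd


@dataclass
class Path:
    """Simple path (no repeated nodes) through strong edges."""

    nodes: list[str]
    step_weights: list[float]
    total_weight: float


def expected_influence(net: WeightedNetwork) -> np.ndarray:
    """One-step expected influence: signed sum of each node's edge weights."""
    return net.weights.sum(axis=1)


def strength(net: WeightedNetwork) -> np.ndarray:
    """Sum of absolute edge weights per node."""
    return np.abs(net.weights).sum(axis=1)


def degree_and_hubs(net: WeightedNetwork,
                    hub_percentile: float = 90.0) -> tuple[np.ndarray, list[str]]:
    """Edge counts per node and the hub set.

    Hubs are nodes whose degree reaches the given percentile of the degree
    distribution (ties included); an edgeless network has no hubs.
    """
    deg = net.adjacency().sum(axis=1)
    if deg.max() == 0:
        return deg, []
    cut = np.percentile(deg, hub_percentile)
    hubs = [net.node_labels[i] for i in range(net.k) if deg[i] >= cut]
    return deg, hubs


def clustering(net: WeightedNetwork) -> np.ndarray:
    """Onnela weighted clustering on max-normalized absolute weights.

    ``C_i = (1/(d_i (d_i - 1))) * sum_{j,h} (w_ij w_ih w_jh)^(1/3)`` with
    weights ``|w| / max|w|``; nodes with degree < 2 get 0.
    """
    A = np.abs(net.weights).copy()
    A[A < ABSENT_TOL] = 0.0
    mx = A.max()
    if mx == 0:
        return np.zeros(net.k)
    W13 = np.cbrt(A / mx)
    tri = np.diag(W13 @ W13 @ W13)
    deg = (A > 0).sum(axis=1)
    denom = deg * (deg - 1)
    out = np.zeros(net.k)
    nz = denom > 0
    out[nz] = tri[nz] / denom[nz]
    return np.clip(out, 0.0, 1.0)


def _shortest_path_lengths(net: WeightedNetwork) -> np.ndarray:
    A = np.abs(net.weights).copy()
    A[A < ABSENT_TOL] = 0.0
    with np.errstate(divide="ignore"):
        lengths = np.where(A > 0, 1.0 / A, 0.0)
    return dijkstra(csr_matrix(lengths), directed=False)


def efficiency(net: WeightedNetwork) -> tuple[float, np.ndarray]:
    """(global efficiency, per-node efficiency).

    Edge lengths are ``1/|w|``; efficiency is the mean inverse weighted
    shortest-path length, disconnected pairs contributing zero.
    """
    k = net.k
    if k < 2:
        return 0.0, np.zeros(k)
    D = _shortest_path_lengths(net)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(D) & (D > 0), 1.0 / D, 0.0)
    np.fill_diagonal(inv, 0.0)
    nodal = inv.sum(axis=1) / (k - 1)
    glob = inv.sum() / (k * (k - 1))
    return float(glob), nodal


def centrality_table(net: WeightedNetwork,
                     hub_percentile: float = 90.0) -> CentralityTable:
    """All centrality indices for one layer in a single table."""
    deg, hubs = degree_and_hubs(net, hub_percentile)
    glob, nodal = efficiency(net)
    return CentralityTable(
        node_labels=list(net.node_labels),
        expected_influence=expected_influence(net),
        strength=strength(net),
        degree=deg,
        clustering=clustering(net),
        nodal_efficiency=nodal,
        global_efficiency=glob,
        layer=net.layer,
        meta={"hubs": hubs, "hub_percentile": hub_percentile,
              "clustering_variant": "onnela-abs"},
    )


class _EnumerationOverflow(Exception):
    pass


def _maximal_simple_paths(adj: dict[int, set[int]], cap: int = 500000):
    """All maximal simple paths (not extendable at either end), deduplicated.

    Canonical orientation: lexicographically smaller endpoint first.  Raises
    :class:`_EnumerationOverflow` past ``cap`` extension steps (dense graphs
    have exponentially many simple paths).
    """
    out = set()
    count = 0

    def extend(path, visited):
        nonlocal count
        tail = path[-1]
        nxt = [v for v in adj[tail] if v not in visited]
        if not nxt:
            head = path[0]
            if all(v in visited for v in adj[head]):  # head not extendable
                canon = tuple(path) if path[0] <= path[-1] else tuple(path[::-1])
                out.add(canon)
            return
        for v in sorted(nxt):
            count += 1
            if count > cap:
                raise _EnumerationOverflow
            visited.add(v)
            extend(path + [v], visited)
            visited.remove(v)

    for s in sorted(adj):
        extend([s], {s})
    return [list(p) for p in out]


def _greedy_paths(A: np.ndarray, adj: dict[int, set[int]],
                  max_paths: int) -> list[list[int]]:
    """Deterministic greedy path extraction for graphs too dense to enumerate.

    Seeds each path with the strongest remaining edge and extends both ends
    by the strongest edge to an unused node (ties broken by node index).
    """
    used: set[int] = set()
    paths = []
    while len(paths) < max_paths:
        best = None
        for i in adj:
            if i in used:
                continue
            for j in adj[i]:
                if j in used or j <= i:
                    continue
                if best is None or A[i, j] > A[best] + 1e-15:
                    best = (i, j)
        if best is None:
            break
        path = list(best)
        in_path = set(path)
        grew = True
        while grew:
            grew = False
            for end, pos in ((path[-1], "tail"), (path[0], "head")):
                cands = [v for v in adj[end]
                         if v not in in_path and v not in used]
                if not cands:
                    continue
                v = max(cands, key=lambda u: (A[end, u], -u))
                if pos == "tail":
                    path.append(v)
                else:
                    path.insert(0, v)
                in_path.add(v)
                grew = True
        if path[0] > path[-1]:
            path.reverse()
        paths.append(path)
        used |= in_path
    return paths


def find_paths(net: WeightedNetwork, threshold: float = 0.15,
               max_paths: int = 5) -> list[Path]:
    """Strong, mutually node-disjoint simple paths.

    Keeps edges with ``|w| >= threshold``, enumerates all maximal simple
    paths of the thresholded graph, ranks them by total absolute weight and
    greedily selects up to ``max_paths`` node-disjoint paths of at least two
    edges.  Deterministic: ties break on the lexicographic node sequence.
    On graphs too dense for exact enumeration, a deterministic greedy
    strongest-edge extraction is used instead (with a warning).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    k = net.k
    A = np.abs(net.weights)
    adj = {i: {j for j in range(k)
               if j != i and A[i, j] >= threshold} for i in range(k)}
    adj = {i: s for i, s in adj.items() if s}
    if not adj:
        return []
    try:
        raw = _maximal_simple_paths(adj)
    except _EnumerationOverflow:
        warnings.warn("thresholded graph too dense for exhaustive path "
                      "enumeration; falling back to greedy extraction")
        raw = _greedy_paths(A, adj, max_paths)
    scored = []
    for p in raw:
        if len(p) < 3:  # need >= 2 edges
            continue
        tw = float(sum(A[a, b] for a, b in zip(p[:-1], p[1:])))
        scored.append((tw, [net.node_labels[i] for i in p], p))
    scored.sort(key=lambda t: (-t[0], t[1]))
    chosen: list[Path] = []
    used: set[int] = set()
    for tw, labels, p in scored:
        if len(chosen) >= max_paths:
            break
        if used & set(p):
            continue
        steps = [float(net.weights[a, b]) for a, b in zip(p[:-1], p[1:])]
        chosen.append(Path(nodes=labels, step_weights=steps, total_weight=tw))
        used |= set(p)
    return chosen


def fr_layout(net: WeightedNetwork, iterations: int = 500,
              seed: int = 0) -> dict[str, tuple[float, float]]:
    """Fruchterman-Reingold layout with attraction proportional to |w|.

    Coordinates are rescaled to the unit square; deterministic given seed.
    """
    import networkx as nx

    if net.k == 0:
        return {}
    if net.k == 1:
        return {net.node_labels[0]: (0.0, 0.0)}
    G = nx.Graph()
    G.add_nodes_from(net.node_labels)
    for a, b, w in net.edge_list():
        G.add_edge(a, b, absw=abs(w))
    pos = nx.spring_layout(G, weight="absw", iterations=iterations, seed=seed)
    xy = np.array([pos[n] for n in net.node_labels])
    lo, hi = xy.min(axis=0), xy.max(axis=0)
    span = np.where(hi - lo > 0, hi - lo, 1.0)
    xy = (xy - lo) / span
    return {n: (float(x), float(y)) for n, (x, y) in zip(net.node_labels, xy)}
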