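"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the library code paths they check:
clustering by explicit triple enumeration, shortest paths by a hand-rolled
Dijkstra, community optima by exhaustive set-partition search.
"""

from __future__ import annotations

import heapq
import itertools

import numpy as np
import pytest

from psychonectome.ggm import WeightedNetwork


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_weighted_network(rng, k: int, p_edge: float = 0.5,
                            w_range=(-0.6, 0.6)) -> WeightedNetwork:
    W = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            if rng.random() < p_edge:
                W[i, j] = W[j, i] = rng.uniform(*w_range)
    return WeightedNetwork(node_labels=[f"N{i}" for i in range(k)], weights=W)


# ---------------------------------------------------------------------------
# brute-force topology oracles

def brute_clustering(W: np.ndarray) -> np.ndarray:
    """Onnela clustering by explicit O(k^3) triple enumeration."""
    k = W.shape[0]
    A = np.abs(W)
    mx = A.max()
    out = np.zeros(k)
    if mx == 0:
        return out
    Wn = A / mx
    for i in range(k):
        nbr = [j for j in range(k) if A[i, j] >= 1e-8]
        d = len(nbr)
        if d < 2:
            continue
        s = 0.0
        for j in nbr:
            for h in nbr:
                if j != h and A[j, h] >= 1e-8:
                    s += (Wn[i, j] * Wn[i, h] * Wn[j, h]) ** (1.0 / 3.0)
        out[i] = s / (d * (d - 1))
    return out


def brute_efficiency(W: np.ndarray) -> tuple[float, np.ndarray]:
    """Global/nodal efficiency via an independent Dijkstra on 1/|w| lengths."""
    k = W.shape[0]
    A = np.abs(W)
    INF = float("inf")
    inv = np.zeros((k, k))
    for s in range(k):
        dist = [INF] * k
        dist[s] = 0.0
        pq = [(0.0, s)]
        while pq:
            d, u = heapq.heappop(pq)
            if d > dist[u]:
                continue
            for v in range(k):
                if A[u, v] >= 1e-8:
                    nd = d + 1.0 / A[u, v]
                    if nd < dist[v] - 1e-15:
                        dist[v] = nd
                        heapq.heappush(pq, (nd, v))
        for t in range(k):
            if t != s and np.isfinite(dist[t]) and dist[t] > 0:
                inv[s, t] = 1.0 / dist[t]
    return inv.sum() / (k * (k - 1)), inv.sum(axis=1) / (k - 1)


# ---------------------------------------------------------------------------
# brute-force community oracle

def all_set_partitions(n: int):
    """Every partition of range(n) as a label vector (restricted growth)."""
    def rec(prefix):
        if len(prefix) == n:
            yield list(prefix)
            return
        m = max(prefix) + 1 if prefix else 0
        for c in range(m + 1):
            yield from rec(prefix + [c])
    yield from rec([])


def brute_min_hamiltonian(J: np.ndarray) -> tuple[float, list[int]]:
    """Exhaustive minimum of H = -sum_{i<j} J_ij [sigma_i == sigma_j]."""
    k = J.shape[0]
    iu = np.triu_indices(k, 1)
    Ju = J[iu]
    best_h, best_p = np.inf, None
    for p in all_set_partitions(k):
        sig = np.asarray(p)
        same = (sig[iu[0]] == sig[iu[1]])
        H = -float(Ju[same].sum())
        if H < best_h - 1e-12:
            best_h, best_p = H, p
    return best_h, best_p


def two_block_network(k: int = 8, w_in: float = 0.3,
                      w_between: float = 0.05) -> WeightedNetwork:
    """Planted two-block signed test network (blocks of k/2)."""
    h = k // 2
    W = np.zeros((k, k))
    for i in range(h):
        for j in range(i + 1, h):
            W[i, j] = W[j, i] = w_in
    for i in range(h, k):
        for j in range(i + 1, k):
            W[i, j] = W[j, i] = w_in
    W[0, h] = W[h, 0] = w_between
    return WeightedNetwork(node_labels=[f"N{i}" for i in range(k)], weights=W)


def pair_counting_ari(x: list[int], y: list[int]) -> float:
    """Adjusted Rand index by direct pair counting (independent oracle)."""
    n = len(x)
    ss = sd = ds = dd = 0
    for i, j in itertools.combinations(range(n), 2):
        a = x[i] == x[j]
        b = y[i] == y[j]
        ss += a and b
        sd += a and not b
        ds += (not a) and b
        dd += (not a) and (not b)
    total = ss + sd + ds + dd
    exp = (ss + sd) * (ss + ds) / total
    mx = 0.5 * ((ss + sd) + (ss + ds))
    if mx == exp:
        return 1.0
    return (ss - exp) / (mx - exp)
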