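"""Spinglass community detection on signed weighted networks.

Partitions minimize the signed Reichardt-Bornholdt Potts Hamiltonian

    H(sigma) = - sum_{i<j} [w+_ij - gamma * p+_ij] * delta(sigma_i, sigma_j)
               + sum_{i<j} [w-_ij - gamma * p-_ij] * delta(sigma_i, sigma_j)

where ``w+``/``w-`` are the positive/negative parts of the weight matrix and
``p+-_ij = s_i s_j / (2 m)`` are weighted configuration-model expectations
computed within each sign layer.  Optimization is single-node Metropolis
simulated annealing with a geometric cooling schedule.  Defaults follow the
conventional psychometric setup: gamma = 1, start temperature 1, stop
temperature 0.01, cooling factor 0.99, up to 25 spin states.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score

from .ggm import ABSENT_TOL, WeightedNetwork

__all__ = [
    "SpinglassParams",
    "Partition",
    "coupling_matrix",
    "hamiltonian",
    "spinglass",
    "compare_partitions",
]


@dataclass
class SpinglassParams:
    gamma: float = 1.0
    start_temp: float = 1.0
    stop_temp: float = 0.01
    cooling_factor: float = 0.99
    spins: int = 25
    sweeps_per_temp: int | None = None  # default: one sweep per node (k)
    seed: int = 0
    restarts: int = 1

    def validate(self) -> None:
        if not (0 < self.stop_temp < self.start_temp):
            raise ValueError("need 0 < stop_temp < start_temp")
        if not (0 < self.cooling_factor < 1):
            raise ValueError("cooling_factor must be in (0, 1)")
        if self.spins < 2:
            raise ValueError("spins must be >= 2")


@dataclass
class Partition:
    """Node -> community assignment with the attained Hamiltonian."""

    assignment: dict[str, int]
    n_communities: int
    hamiltonian: float
    params: SpinglassParams | None = None

    def labels_for(self, node_labels: list[str]) -> np.ndarray:
        try:
            return np.array([self.assignment[n] for n in node_labels])
        except KeyError as e:
            raise ValueError(f"partition does not cover node {e}") from None


def coupling_matrix(net: WeightedNetwork, gamma: float = 1.0) -> np.ndarray:
    """Effective coupling J with H = -sum_{i<j} J_ij delta(sigma_i, sigma_j).

    ``J = (w+ - gamma p+) - (w- - gamma p-)`` combining both sign layers.
    """
    W = net.weights.copy()
    W[np.abs(W) < ABSENT_TOL] = 0.0
    J = np.zeros_like(W)
    for sgn in (1.0, -1.0):
        L = np.clip(sgn * W, 0.0, None)
        s = L.sum(axis=1)
        two_m = s.sum()
        P = np.outer(s, s) / two_m if two_m > 0 else np.zeros_like(L)
        np.fill_diagonal(P, 0.0)
        J += sgn * (L - gamma * P)
    np.fill_diagonal(J, 0.0)
    return J


def hamiltonian(net: WeightedNetwork, partition: Partition | dict,
                gamma: float = 1.0) -> float:
    """Evaluate the signed Potts Hamiltonian of a partition."""
    assignment = partition.assignment if isinstance(partition, Partition) else partition
    try:
        sigma = np.array([assignment[n] for n in net.node_labels])
    except KeyError as e:
        raise ValueError(f"partition does not assign node {e}") from None
    J = coupling_matrix(net, gamma)
    same = sigma[:, None] == sigma[None, :]
    return float(-np.sum(np.triu(J * same, 1)))


def _anneal(J: np.ndarray, params: SpinglassParams, seed: int) -> tuple[np.ndarray, float]:
    rng = np.random.default_rng(seed)
    k = J.shape[0]
    spins = min(params.spins, k)
    sweeps = params.sweeps_per_temp if params.sweeps_per_temp is not None else k
    sigma = rng.integers(0, spins, size=k)
    M = np.zeros((k, spins))
    for c in range(spins):
        M[:, c] = J[:, sigma == c].sum(axis=1)

    T = params.start_temp
    n_moves = sweeps * k
    while T >= params.stop_temp:
        nodes = rng.integers(0, k, size=n_moves)
        props = rng.integers(0, spins, size=n_moves)
        us = rng.random(n_moves)
        for i, c_new, u in zip(nodes, props, us):
            c_old = sigma[i]
            if c_new == c_old:
                continue
            dH = M[i, c_old] - M[i, c_new]
            if dH <= 0.0 or u < np.exp(-dH / T):
                sigma[i] = c_new
                M[:, c_old] -= J[:, i]
                M[:, c_new] += J[:, i]
        T *= params.cooling_factor

    # greedy zero-temperature polish to the nearest local minimum
    improved = True
    while improved:
        improved = False
        for i in range(k):
            c_old = sigma[i]
            c_best = int(np.argmax(M[i]))
            if M[i, c_best] > M[i, c_old] + 1e-12:
                sigma[i] = c_best
                M[:, c_old] -= J[:, i]
                M[:, c_best] += J[:, i]
                improved = True

    same = sigma[:, None] == sigma[None, :]
    H = float(-np.sum(np.triu(J * same, 1)))
    return sigma, H


def spinglass(net: WeightedNetwork,
              params: SpinglassParams | None = None) -> Partition:
    """Signed spinglass community detection by simulated annealing.

    Deterministic given ``params.seed``; with ``restarts > 1`` the best of
    several independently seeded runs (by Hamiltonian) is returned.  An
    edgeless network yields singleton communities with a warning.
    """
    if params is None:
        params = SpinglassParams()
    params.validate()
    k = net.k
    if np.all(np.abs(net.weights) < ABSENT_TOL):
        warnings.warn("edgeless network: every node is its own community")
        assignment = {n: i for i, n in enumerate(net.node_labels)}
        return Partition(assignment=assignment, n_communities=k,
                         hamiltonian=0.0, params=params)
    J = coupling_matrix(net, params.gamma)
    best_sigma, best_H = None, np.inf
    for r in range(max(1, params.restarts)):
        sigma, H = _anneal(J, params, seed=params.seed + 7919 * r)
        if H < best_H - 1e-12:
            best_sigma, best_H = sigma, H
    # relabel to consecutive ids ordered by first occurrence
    relabel: dict[int, int] = {}
    out = np.empty(k, dtype=int)
    for i, c in enumerate(best_sigma):
        if c not in relabel:
            relabel[c] = len(relabel)
        out[i] = relabel[c]
    assignment = {n: int(c) for n, c in zip(net.node_labels, out)}
    return Partition(assignment=assignment, n_communities=len(relabel),
                     hamiltonian=best_H, params=params)


def compare_partitions(p1: Partition | dict,
                       p2: Partition | dict) -> tuple[float, float]:
    """(adjusted Rand index, normalized mutual information) of two partitions."""
    a1 = p1.assignment if isinstance(p1, Partition) else dict(p1)
    a2 = p2.assignment if isinstance(p2, Partition) else dict(p2)
    if set(a1) != set(a2):
        raise ValueError("partitions cover different node sets")
    nodes = sorted(a1)
    x = [a1[n] for n in nodes]
    y = [a2[n] for n in nodes]
    ari = float(adjusted_rand_score(x, y))
    nmi = float(normalized_mutual_info_score(x, y))
    return ari, nmi
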