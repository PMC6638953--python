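"""Synthetic pre/post questionnaire cohorts with a planted partial-correlation structure.

The study data this package was designed around are not publicly deposited, so
validation runs on cohorts drawn from a *planted network*: a user-specified
sparse signed partial-correlation structure (chains of construct-to-construct
"paths", block "communities", isolated negative edges).  Subscale scores are
generated through a Gaussian copula: latent multivariate-normal draws whose
precision matrix encodes the planted partial correlations, discretized to an
ordinal Likert grid.  The module also plants within-subject dependence across
the two measurement occasions and MCAR missingness.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DEFAULT_NODE_LABELS",
    "PlantedNetwork",
    "Cohort",
    "make_planted_network",
    "sample_cohort",
    "make_pre_post",
    "apply_mcar",
    "write_cohort",
    "read_cohort",
    "write_planted_network",
    "read_planted_network",
]

#: The 25 subscale acronyms used as default node labels (five construct
#: families: mindfulness, compassion, well-being, distress, emotional and
#: cognitive control).
DEFAULT_NODE_LABELS = [
    "FFMQ-O", "FFMQ-D", "FFMQ-A", "FFMQ-J", "FFMQ-R",
    "NAS", "EQ", "MAIA",
    "SCS-A", "SCS-H", "SCS-M", "CSP", "IRI-E",
    "SWLS", "LOT", "PHI",
    "DASS-D", "DASS-A", "DASS-S",
    "WBSI", "RRS-B", "RRS-R", "ERQ-R", "ERQ-S", "ACS",
]

#: Construct family of each default node, for table metadata.
DEFAULT_FAMILIES = {
    **{x: "mindfulness" for x in ["FFMQ-O", "FFMQ-D", "FFMQ-A", "FFMQ-J",
                                  "FFMQ-R", "NAS", "EQ", "MAIA"]},
    **{x: "compassion" for x in ["SCS-A", "SCS-H", "SCS-M", "CSP", "IRI-E"]},
    **{x: "well-being" for x in ["SWLS", "LOT", "PHI"]},
    **{x: "distress" for x in ["DASS-D", "DASS-A", "DASS-S"]},
    **{x: "emotional-cognitive control" for x in ["WBSI", "RRS-B", "RRS-R",
                                                  "ERQ-R", "ERQ-S", "ACS"]},
}


class InvalidParameterError(ValueError):
    """A generator parameter is outside its admissible range."""


class EdgeConflictError(ValueError):
    """The same edge was requested twice with different weights."""


class SchemaError(ValueError):
    """Mismatched labels / subject ids between paired objects."""


@dataclass
class PlantedNetwork:
    """Ground-truth signed sparse partial-correlation structure.

    ``pcor`` holds *realized* partial correlations: if the requested structure
    implies an indefinite precision matrix, a minimal ridge inflation is
    applied and the (uniformly shrunk) result becomes the declared truth.
    """

    node_labels: list[str]
    pcor: np.ndarray
    communities: dict[str, int]
    description: str = ""

    @property
    def k(self) -> int:
        return len(self.node_labels)

    def precision(self) -> np.ndarray:
        """Unit-diagonal precision matrix implied by ``pcor``."""
        K = -np.asarray(self.pcor, dtype=float).copy()
        np.fill_diagonal(K, 1.0)
        return K

    def implied_correlation(self) -> np.ndarray:
        """Marginal latent correlation matrix (standardized inverse precision)."""
        sigma = np.linalg.inv(self.precision())
        d = np.sqrt(np.diag(sigma))
        R = sigma / np.outer(d, d)
        np.fill_diagonal(R, 1.0)
        return (R + R.T) / 2.0

    def edge_list(self) -> list[tuple[str, str, float]]:
        out = []
        for i in range(self.k):
            for j in range(i + 1, self.k):
                if abs(self.pcor[i, j]) >= 1e-12:
                    out.append((self.node_labels[i], self.node_labels[j],
                                float(self.pcor[i, j])))
        return out


@dataclass
class Cohort:
    """Subject × node ordinal score matrix for one measurement occasion.

    ``scores`` contains values in {1..levels} when ``levels`` > 0, continuous
    latent values when ``levels`` == 0.  Masked entries (``missing_mask``
    True) are NaN in ``scores``.
    """

    scores: np.ndarray
    occasion: str
    levels: int
    missing_mask: np.ndarray
    node_labels: list[str]
    subject_ids: list[str]
    latent: np.ndarray | None = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return self.scores.shape[0]

    @property
    def k(self) -> int:
        return self.scores.shape[1]

    def observed(self) -> np.ndarray:
        """Scores with masked entries as NaN."""
        out = self.scores.astype(float).copy()
        out[self.missing_mask] = np.nan
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.observed(), columns=self.node_labels,
                            index=self.subject_ids)


def _resolve(label_or_idx, labels: list[str]) -> int:
    if isinstance(label_or_idx, (int, np.integer)):
        idx = int(label_or_idx)
        if not 0 <= idx < len(labels):
            raise InvalidParameterError(f"node index {idx} out of range")
        return idx
    try:
        return labels.index(label_or_idx)
    except ValueError:
        raise InvalidParameterError(f"unknown node label {label_or_idx!r}") from None


def _check_weight(w: float) -> float:
    w = float(w)
    if not (-1.0 < w < 1.0):
        raise InvalidParameterError(f"edge weight {w} outside (-1, 1)")
    return w


def make_planted_network(
    k: int | None = None,
    chain_specs=(),
    block_specs=(),
    negative_edges=(),
    node_labels: list[str] | None = None,
    description: str = "",
    seed: int | None = None,
) -> PlantedNetwork:
    """Assemble a planted partial-correlation network.

    Parameters
    ----------
    k
        Node count.  Defaults to 25 (the default label set).
    chain_specs
        List of ``(node_sequence, weight_sequence)``: consecutive nodes in the
        sequence are connected with the given partial correlations, encoding a
        network "path".
    block_specs
        List of ``(node_set, within_weight)``: all pairs inside the set get
        the within weight, and the set becomes one planted community.  Chain
        and negative-edge weights take precedence over block weights on
        overlapping pairs; conflicting duplicates *within* the same spec kind
        raise :class:`EdgeConflictError`.
    negative_edges
        List of ``(i, j, weight)`` extra (typically negative) edges.
    seed
        Unused by the deterministic assembly; accepted for interface symmetry.

    Notes
    -----
    The precision matrix is assembled with unit diagonal and off-diagonal
    entries ``-pcor_ij``.  If it is not positive definite, the smallest ridge
    ``delta`` (binary search, tolerance 1e-8) making the minimum eigenvalue of
    ``K + delta*I`` at least 1e-6 is added and the matrix rescaled back to
    unit diagonal, which shrinks every requested weight by ``1/(1+delta)``.
    The returned (realized) ``pcor`` is recomputed from the repaired matrix.
    """
    if node_labels is None:
        if k is None or k == len(DEFAULT_NODE_LABELS):
            node_labels = list(DEFAULT_NODE_LABELS)
        else:
            node_labels = [f"V{i + 1}" for i in range(k)]
    else:
        node_labels = list(node_labels)
    if k is None:
        k = len(node_labels)
    if k != len(node_labels):
        raise InvalidParameterError("k does not match node_labels length")

    pcor = np.zeros((k, k))
    set_by = np.zeros((k, k), dtype=int)  # 0 unset, 1 chain, 2 negedge, 3 block

    def place(i, j, w, kind):
        if i == j:
            raise InvalidParameterError("self-edges are not allowed")
        prev = set_by[i, j]
        if prev == kind and not np.isclose(pcor[i, j], w):
            raise EdgeConflictError(
                f"edge ({node_labels[i]}, {node_labels[j]}) given conflicting "
                f"weights {pcor[i, j]} and {w}")
        if prev != 0 and prev < kind:
            return  # lower kind number wins (chains > negative edges > blocks)
        pcor[i, j] = pcor[j, i] = w
        set_by[i, j] = set_by[j, i] = kind

    for nodes, weights in chain_specs:
        idx = [_resolve(x, node_labels) for x in nodes]
        if len(weights) != len(idx) - 1:
            raise InvalidParameterError("chain needs len(nodes)-1 weights")
        for a, b, w in zip(idx[:-1], idx[1:], weights):
            place(a, b, _check_weight(w), 1)
    for i, j, w in negative_edges:
        place(_resolve(i, node_labels), _resolve(j, node_labels),
              _check_weight(w), 2)
    communities: dict[str, int] = {}
    for cid, (nodes, w) in enumerate(block_specs):
        idx = [_resolve(x, node_labels) for x in nodes]
        w = _check_weight(w)
        for a in idx:
            if node_labels[a] in communities:
                raise InvalidParameterError(
                    f"node {node_labels[a]} assigned to two communities")
            communities[node_labels[a]] = cid
        if abs(w) >= 1e-12:
            for ii, a in enumerate(idx):
                for b in idx[ii + 1:]:
                    place(a, b, w, 3)
    next_cid = len(block_specs)
    for lab in node_labels:
        if lab not in communities:
            communities[lab] = next_cid
            next_cid += 1

    K = -pcor.copy()
    np.fill_diagonal(K, 1.0)
    lam_min = float(np.linalg.eigvalsh(K)[0])
    if lam_min < 1e-6:
        # smallest delta with min-eig(K + delta I) >= 1e-6, to 1e-8
        lo, hi = 0.0, (1e-6 - lam_min) + 1.0
        while hi - lo > 1e-8:
            mid = (lo + hi) / 2.0
            if lam_min + mid >= 1e-6:
                hi = mid
            else:
                lo = mid
        delta = hi
        K = (K + delta * np.eye(k)) / (1.0 + delta)
        pcor = -K.copy()
        np.fill_diagonal(pcor, 0.0)

    return PlantedNetwork(node_labels=node_labels, pcor=pcor,
                          communities=communities, description=description)


def random_sparse_network(
    k: int = 25,
    density: float = 0.15,
    weight_range: tuple[float, float] = (0.2, 0.45),
    neg_fraction: float = 0.2,
    row_budget: float = 0.95,
    max_degree: int = 5,
    node_labels: list[str] | None = None,
    seed: int = 0,
) -> PlantedNetwork:
    """Random sparse planted network with guaranteed-feasible strong edges.

    Draws a random graph at the requested density (degree capped) and assigns
    signed weights from ``weight_range`` subject to a per-node budget on the
    total absolute partial correlation (``row_budget`` < 1 keeps the
    precision matrix diagonally dominant, hence positive definite, so the
    realized weights equal the requested ones exactly).  Edges that cannot
    fit the minimum weight under the remaining budget are redrawn elsewhere.
    """
    rng = np.random.default_rng(seed)
    w_lo, w_hi = weight_range
    if not (0 < w_lo <= w_hi < 1):
        raise InvalidParameterError("weight_range must satisfy 0 < lo <= hi < 1")
    n_edges = int(round(density * k * (k - 1) / 2))
    if 2 * n_edges * w_lo > k * row_budget:
        raise InvalidParameterError(
            "requested density/minimum weight exceed the per-node budget")
    if node_labels is None:
        node_labels = [f"V{i + 1}" for i in range(k)]

    # the minimum weight fixes the admissible degree under the budget
    deg_cap = min(max_degree, int(row_budget / w_lo))
    if n_edges * 2 > deg_cap * k:
        raise InvalidParameterError(
            "requested density infeasible under the per-node weight budget")
    degree = np.zeros(k, dtype=int)
    chosen: set[tuple[int, int]] = set()
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    attempts = 0
    while len(chosen) < n_edges:
        attempts += 1
        if attempts > 200 * n_edges:
            raise InvalidParameterError(
                f"could only place {len(chosen)} of {n_edges} edges; relax "
                "the density, weights or degree cap")
        i, j = pairs[rng.integers(len(pairs))]
        if (i, j) in chosen or degree[i] >= deg_cap or degree[j] >= deg_cap:
            continue
        chosen.add((i, j))
        degree[i] += 1
        degree[j] += 1
    # start every edge at the minimum weight, then spread the leftover
    # per-node budget in random passes
    edge_idx = sorted(chosen)
    w = np.full(len(edge_idx), w_lo)
    slack = row_budget - w_lo * degree
    for _ in range(4):
        for e in rng.permutation(len(edge_idx)):
            i, j = edge_idx[e]
            room = min(slack[i], slack[j], w_hi - w[e])
            if room <= 0:
                continue
            add = rng.uniform(0.0, room)
            w[e] += add
            slack[i] -= add
            slack[j] -= add
    signs = np.where(rng.random(len(edge_idx)) < neg_fraction, -1.0, 1.0)
    edges = [(i, j, float(s * wt))
             for (i, j), s, wt in zip(edge_idx, signs, w)]
    return make_planted_network(k, negative_edges=edges,
                                node_labels=node_labels,
                                description=f"random sparse (seed={seed})")


def _discretize(z: np.ndarray, levels: int,
                thresholds: np.ndarray | None = None) -> np.ndarray:
    """Latent normals -> ordinal codes 1..levels via quantile thresholds."""
    if thresholds is None:
        thresholds = stats.norm.ppf(np.arange(1, levels) / levels)
    return 1 + np.searchsorted(thresholds, z).reshape(z.shape)


def sample_cohort(
    net: PlantedNetwork,
    n: int = 182,
    levels: int = 5,
    occasion: str = "pre",
    seed: int = 0,
    thresholds: np.ndarray | None = None,
) -> Cohort:
    """Draw a cohort from the Gaussian copula implied by a planted network.

    Latent multivariate-normal vectors with the network's implied correlation
    matrix are discretized per margin by ``levels - 1`` equal-probability
    normal quantile thresholds (``levels=0`` keeps the continuous latents).
    Deterministic given ``seed``.
    """
    if n < 2:
        raise InvalidParameterError("need at least 2 subjects")
    if levels != 0 and levels < 2:
        raise InvalidParameterError("levels must be 0 (continuous) or >= 2")
    rng = np.random.default_rng(seed)
    R = net.implied_correlation()
    L = np.linalg.cholesky(R)
    z = rng.standard_normal((n, net.k)) @ L.T
    scores = z if levels == 0 else _discretize(z, levels, thresholds).astype(float)
    return Cohort(
        scores=scores,
        occasion=occasion,
        levels=levels,
        missing_mask=np.zeros((n, net.k), dtype=bool),
        node_labels=list(net.node_labels),
        subject_ids=[f"S{i + 1:04d}" for i in range(n)],
        latent=z,
    )


def make_pre_post(
    pre_net: PlantedNetwork,
    post_net: PlantedNetwork,
    n: int = 182,
    subject_rho: float = 0.4,
    levels: int = 5,
    seed: int = 0,
) -> tuple[Cohort, Cohort]:
    """Paired pre/post cohorts with a shared subject-level latent component.

    Each occasion's latent vector is ``L_occ @ (sqrt(rho) u + sqrt(1-rho) e)``
    with ``u`` shared between occasions and ``e`` occasion-specific, so each
    occasion keeps its own network's correlation structure exactly while the
    per-node pre/post latent correlation is ``subject_rho`` (exactly so when
    the two networks coincide).
    """
    if pre_net.node_labels != post_net.node_labels:
        raise SchemaError("pre and post networks must share node labels")
    if not (0.0 <= subject_rho < 1.0):
        raise InvalidParameterError("subject_rho must be in [0, 1)")
    rng = np.random.default_rng(seed)
    k = pre_net.k
    u = rng.standard_normal((n, k))
    cohorts = []
    for net, occ in ((pre_net, "pre"), (post_net, "post")):
        e = rng.standard_normal((n, k))
        base = np.sqrt(subject_rho) * u + np.sqrt(1.0 - subject_rho) * e
        L = np.linalg.cholesky(net.implied_correlation())
        z = base @ L.T
        scores = z if levels == 0 else _discretize(z, levels).astype(float)
        cohorts.append(Cohort(
            scores=scores, occasion=occ, levels=levels,
            missing_mask=np.zeros((n, k), dtype=bool),
            node_labels=list(net.node_labels),
            subject_ids=[f"S{i + 1:04d}" for i in range(n)],
            latent=z,
        ))
    return cohorts[0], cohorts[1]


def apply_mcar(cohort: Cohort, rate: float, seed: int = 0) -> Cohort:
    """Mask entries independently with probability ``rate`` (MCAR).

    Missingness is independent of all observed and latent values.
    """
    if not (0.0 <= rate <= 0.5):
        raise InvalidParameterError("MCAR rate must be in [0, 0.5]")
    rng = np.random.default_rng(seed)
    mask = cohort.missing_mask | (rng.random(cohort.scores.shape) < rate)
    return replace(cohort, missing_mask=mask)


# ---------------------------------------------------------------------------
# on-disk formats

def write_cohort(cohort: Cohort, csv_path, sidecar_path=None, seed=None,
                 truth_reference: str = "") -> None:
    """CSV (header = node labels, empty cell = missing) + JSON sidecar."""
    cohort.to_frame().to_csv(csv_path, index_label="subject_id")
    if sidecar_path is None:
        sidecar_path = str(csv_path) + ".json"
    meta = {"occasion": cohort.occasion, "levels": cohort.levels,
            "seed": seed, "truth_reference": truth_reference}
    with open(sidecar_path, "w") as fh:
        json.dump(meta, fh, indent=1)


def read_cohort(csv_path, sidecar_path=None) -> Cohort:
    if sidecar_path is None:
        sidecar_path = str(csv_path) + ".json"
    df = pd.read_csv(csv_path, index_col=0)
    try:
        with open(sidecar_path) as fh:
            meta = json.load(fh)
    except FileNotFoundError:
        meta = {"occasion": "other", "levels": 0}
    scores = df.to_numpy(dtype=float)
    mask = np.isnan(scores)
    return Cohort(scores=scores, occasion=meta.get("occasion", "other"),
                  levels=int(meta.get("levels") or 0), missing_mask=mask,
                  node_labels=[str(c) for c in df.columns],
                  subject_ids=[str(i) for i in df.index])


def write_planted_network(net: PlantedNetwork, edges_path, json_path) -> None:
    with open(edges_path, "w") as fh:
        for a, b, w in net.edge_list():
            fh.write(f"{a}\t{b}\t{w:.10g}\n")
    payload = {
        "node_labels": net.node_labels,
        "pcor": [[float(x) for x in row] for row in net.pcor],
        "communities": net.communities,
        "description": net.description,
    }
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_planted_network(json_path) -> PlantedNetwork:
    with open(json_path) as fh:
        payload = json.load(fh)
    return PlantedNetwork(
        node_labels=list(payload["node_labels"]),
        pcor=np.asarray(payload["pcor"], dtype=float),
        communities={str(k): int(v) for k, v in payload["communities"].items()},
        description=payload.get("description", ""),
    )
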