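"""Pre/post analyses: paired univariate tests and network-reorganization
quantification (centrality change, cross-layer correlations, partition
agreement)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ggm import WeightedNetwork
from .synthgen import Cohort, SchemaError
from .topology import CentralityTable

__all__ = [
    "PrePostResult",
    "paired_t",
    "centrality_change",
    "layer_correlation",
    "holm",
]


@dataclass
class PrePostResult:
    tests: pd.DataFrame
    deltas: pd.DataFrame | None = None
    top_movers: dict[str, list[str]] | None = None
    layer_correlations: dict[str, float] | None = None
    partition_ari: float | None = None
    partition_nmi: float | None = None


def paired_t(pre: Cohort, post: Cohort, holm_correction: bool = False) -> pd.DataFrame:
    """Per-node paired Student t-tests on raw (untransformed) scores.

    ``t = dbar / (s_d / sqrt(n))`` with n-1 degrees of freedom, two-sided p.
    Nodes whose differences have zero variance are flagged (t, p = NaN).
    """
    if pre.node_labels != post.node_labels:
        raise SchemaError("pre and post cohorts must share node labels")
    if pre.subject_ids != post.subject_ids:
        raise SchemaError("pre and post cohorts must share subject ids")
    a, b = pre.observed(), post.observed()
    rows = []
    for j, lab in enumerate(pre.node_labels):
        both = ~np.isnan(a[:, j]) & ~np.isnan(b[:, j])
        x, y = a[both, j], b[both, j]
        n = len(x)
        if n < 3:
            raise ValueError(f"node {lab}: fewer than 3 paired observations")
        d = y - x
        sd = d.std(ddof=1)
        if sd == 0.0:
            t = p = np.nan
            flag = "zero-variance differences"
        else:
            t = d.mean() / (sd / np.sqrt(n))
            p = 2.0 * stats.t.sf(abs(t), df=n - 1)
            flag = ""
        rows.append({"node": lab,
                     "pre_mean": x.mean(), "pre_sd": x.std(ddof=1),
                     "post_mean": y.mean(), "post_sd": y.std(ddof=1),
                     "t": t, "df": n - 1, "p": p, "flag": flag})
    df = pd.DataFrame(rows).set_index("node")
    if holm_correction:
        df["p_holm"] = holm(df["p"].to_numpy())
    return df


def holm(pvals: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values (NaNs passed through)."""
    p = np.asarray(pvals, dtype=float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    q = p[ok]
    m = len(q)
    order = np.argsort(q)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * q[idx])
        adj[idx] = min(1.0, running)
    out[ok] = adj
    return out


def centrality_change(pre_table: CentralityTable, post_table: CentralityTable,
                      top: int = 5) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Post-minus-pre deltas per centrality index and the top movers.

    Top movers are the ``top`` nodes with largest |delta| per index.
    """
    if pre_table.node_labels != post_table.node_labels:
        raise SchemaError("centrality tables cover different node sets")
    deltas = post_table.to_frame() - pre_table.to_frame()
    movers = {
        col: list(deltas[col].abs().sort_values(ascending=False).index[:top])
        for col in deltas.columns
    }
    return deltas, movers


def layer_correlation(pre_net: WeightedNetwork, post_net: WeightedNetwork,
                      pre_table: CentralityTable | None = None,
                      post_table: CentralityTable | None = None,
                      ) -> dict[str, float]:
    """Cross-layer Pearson correlations of edge weights and centralities.

    Low values indicate a genuine reorganization of the network between the
    two occasions.  Zero-variance vectors yield NaN (flagged by the caller).
    """
    if pre_net.node_labels != post_net.node_labels:
        raise SchemaError("networks cover different node sets")
    iu = np.triu_indices(pre_net.k, 1)
    out = {"edge_weights": _safe_corr(pre_net.weights[iu], post_net.weights[iu])}
    if pre_table is not None and post_table is not None:
        a, b = pre_table.to_frame(), post_table.to_frame()
        for col in a.columns:
            out[col] = _safe_corr(a[col].to_numpy(dtype=float),
                                  b[col].to_numpy(dtype=float))
    return out


def _safe_corr(x: np.ndarray, y: np.ndarray) -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])
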