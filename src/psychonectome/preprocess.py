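"""Cohort tables -> correlation inputs: EM imputation, Spearman and polychoric
correlation matrices, internal-consistency coefficients.

Imputation follows an intent-to-treat convention: all subjects are retained
and missing entries are completed by multivariate-normal EM on rank-based
normal scores, then mapped back to the ordinal grid.  The network estimator
consumes Spearman-type dependence (ordinal items), while polychoric
correlations back the standardized internal-consistency coefficients.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._bvn import rect_prob
from .synthgen import Cohort

__all__ = [
    "CorrelationMatrix",
    "em_impute",
    "spearman_matrix",
    "polychoric_matrix",
    "cronbach_alpha",
    "write_correlation",
    "read_correlation",
]


@dataclass
class CorrelationMatrix:
    """Symmetric unit-diagonal correlation matrix with per-pair sample sizes."""

    values: np.ndarray
    method: str  # spearman | polychoric | pearson
    n_effective: np.ndarray
    node_labels: list[str]
    repaired: bool = False

    @property
    def k(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.node_labels,
                            columns=self.node_labels)


def blom_scores(x: np.ndarray) -> np.ndarray:
    """Rank-based inverse-normal (Blom) transform of one column.

    Mid-ranks for ties; NaNs are ignored and returned as NaN.  The offset
    ``(rank - 3/8)/(n + 1/4)`` keeps scores finite and near-standard-normal.
    """
    x = np.asarray(x, dtype=float)
    out = np.full(x.shape, np.nan)
    obs = ~np.isnan(x)
    v = x[obs]
    if v.size == 0:
        return out
    if np.nanmax(v) == np.nanmin(v):
        raise ValueError("constant column has no rank-based normal scores")
    ranks = stats.rankdata(v, method="average")
    out[obs] = stats.norm.ppf((ranks - 0.375) / (v.size + 0.25))
    return out


def _psd_repair(R: np.ndarray) -> tuple[np.ndarray, bool]:
    """Clip negative eigenvalues at zero and re-standardize to unit diagonal."""
    w, V = np.linalg.eigh((R + R.T) / 2.0)
    if w[0] >= -1e-8:
        return (R + R.T) / 2.0, False
    w = np.clip(w, 0.0, None)
    S = (V * w) @ V.T
    d = np.sqrt(np.clip(np.diag(S), 1e-12, None))
    S = S / np.outer(d, d)
    np.fill_diagonal(S, 1.0)
    return (S + S.T) / 2.0, True


# ---------------------------------------------------------------------------
# EM imputation

def _mvn_em(Z: np.ndarray, tol: float = 1e-6, max_iter: int = 100):
    """EM for a multivariate normal with MCAR missing entries.

    Returns the completed matrix (conditional means in missing slots), the
    fitted (mu, Sigma) and the number of iterations.
    """
    n, k = Z.shape
    miss = np.isnan(Z)
    mu = np.nanmean(Z, axis=0)
    df = pd.DataFrame(Z)
    Sigma = df.cov(min_periods=2).to_numpy()
    Sigma[np.isnan(Sigma)] = 0.0
    Sigma, _ = _psd_repair_cov(Sigma)

    X = Z.copy()
    X[miss] = np.take(mu, np.where(miss)[1])
    patterns: dict[bytes, np.ndarray] = {}
    for key in np.unique(miss, axis=0):
        rows = np.nonzero((miss == key).all(axis=1))[0]
        patterns[key.tobytes()] = (key, rows)

    ll_old = -np.inf
    for it in range(1, max_iter + 1):
        C = np.zeros((k, k))
        ll = 0.0
        for key, rows in patterns.values():
            o = ~key
            m = key
            Zo = Z[np.ix_(rows, o)]
            if not m.any():
                ll += _mvn_logpdf_sum(Zo, mu[o], Sigma[np.ix_(o, o)])
                continue
            if not o.any():
                X[np.ix_(rows, m)] = mu[m]
                C[np.ix_(m, m)] += len(rows) * Sigma[np.ix_(m, m)]
                continue
            Soo = Sigma[np.ix_(o, o)]
            Smo = Sigma[np.ix_(m, o)]
            sol = np.linalg.solve(Soo + 1e-10 * np.eye(o.sum()), Smo.T).T
            cond_mean = mu[m] + (Zo - mu[o]) @ sol.T
            X[np.ix_(rows, m)] = cond_mean
            cond_cov = Sigma[np.ix_(m, m)] - sol @ Smo.T
            C[np.ix_(m, m)] += len(rows) * cond_cov
            ll += _mvn_logpdf_sum(Zo, mu[o], Soo)
        mu = X.mean(axis=0)
        D = X - mu
        Sigma = (D.T @ D + C) / n
        if ll_old != -np.inf and abs(ll - ll_old) <= tol * abs(ll_old):
            return X, mu, Sigma, it
        ll_old = ll
    warnings.warn("EM did not converge in "
                  f"{max_iter} iterations; returning best iterate")
    return X, mu, Sigma, max_iter


def _conditional_draws(Z: np.ndarray, mu: np.ndarray, Sigma: np.ndarray,
                       seed: int) -> np.ndarray:
    """Fill NaNs in Z with draws from the fitted conditional normal."""
    rng = np.random.default_rng(seed)
    miss = np.isnan(Z)
    X = Z.copy()
    for key in np.unique(miss, axis=0):
        if not key.any():
            continue
        rows = np.nonzero((miss == key).all(axis=1))[0]
        o, m = ~key, key
        if not o.any():
            cm = np.broadcast_to(mu[m], (len(rows), m.sum()))
            cc = Sigma[np.ix_(m, m)]
        else:
            Soo = Sigma[np.ix_(o, o)]
            Smo = Sigma[np.ix_(m, o)]
            sol = np.linalg.solve(Soo + 1e-10 * np.eye(o.sum()), Smo.T).T
            cm = mu[m] + (Z[np.ix_(rows, o)] - mu[o]) @ sol.T
            cc = Sigma[np.ix_(m, m)] - sol @ Smo.T
        w, V = np.linalg.eigh((cc + cc.T) / 2.0)
        half = V * np.sqrt(np.clip(w, 0.0, None))
        noise = rng.standard_normal((len(rows), m.sum())) @ half.T
        X[np.ix_(rows, m)] = cm + noise
    return X


def _psd_repair_cov(S: np.ndarray) -> tuple[np.ndarray, bool]:
    w, V = np.linalg.eigh((S + S.T) / 2.0)
    if w[0] >= 1e-8:
        return (S + S.T) / 2.0, False
    w = np.clip(w, 1e-6, None)
    return (V * w) @ V.T, True


def _mvn_logpdf_sum(Z, mu, S):
    try:
        return float(np.sum(stats.multivariate_normal.logpdf(
            Z, mean=mu, cov=S, allow_singular=True)))
    except np.linalg.LinAlgError:
        return 0.0


def em_impute(cohort: Cohort, method: str = "draw", seed: int = 0) -> Cohort:
    """Complete a cohort by multivariate-normal EM on normal scores.

    Scores are transformed column-wise to rank-based normal scores, the EM
    algorithm is run to convergence (relative log-likelihood change < 1e-6 or
    100 iterations), and the completed scores are mapped back to the ordinal
    grid through each column's marginal category thresholds.  Observed
    entries are returned unchanged.

    ``method="draw"`` (default) fills missing entries with seeded draws from
    the fitted conditional normal distribution (stochastic regression
    imputation), which leaves downstream correlations unbiased;
    ``method="mean"`` fills deterministic conditional means, which slightly
    inflates correlations among strongly related nodes because imputed
    entries carry no residual noise.
    """
    if method not in ("draw", "mean"):
        raise ValueError("method must be 'draw' or 'mean'")
    obs = cohort.observed()
    if not np.isnan(obs).any():
        return cohort
    n, k = obs.shape
    if np.isnan(obs).mean() >= 0.5:
        raise ValueError("more than 50% missing entries; refusing to impute")
    complete_rows = (~np.isnan(obs)).sum(axis=1) >= max(2, k // 2)
    if complete_rows.sum() < 10:
        raise ValueError("fewer than 10 sufficiently observed rows")

    keep = []
    for j in range(k):
        col = obs[:, j]
        v = col[~np.isnan(col)]
        if v.size == 0 or v.max() == v.min():
            warnings.warn(f"column {cohort.node_labels[j]} has zero observed "
                          "variance; dropped from imputation")
        else:
            keep.append(j)
    obs = obs[:, keep]
    labels = [cohort.node_labels[j] for j in keep]
    k = len(keep)

    Z = np.column_stack([blom_scores(obs[:, j]) for j in range(k)])
    X, mu, Sigma, _ = _mvn_em(Z)
    if method == "draw":
        X = _conditional_draws(Z, mu, Sigma, seed)

    filled = obs.copy()
    for j in range(k):
        col = obs[:, j]
        miss = np.isnan(col)
        if not miss.any():
            continue
        v = col[~miss]
        if cohort.levels > 0:
            cats = np.arange(1, cohort.levels + 1, dtype=float)
            props = np.array([(v == c).mean() for c in cats])
            cum = np.cumsum(props)[:-1]
            thr = stats.norm.ppf(np.clip(cum, 1e-9, 1 - 1e-9))
            filled[miss, j] = 1.0 + np.searchsorted(thr, X[miss, j])
        else:
            # continuous margin: empirical quantile back-transform
            order = np.argsort(v)
            q = stats.norm.cdf(X[miss, j])
            filled[miss, j] = np.quantile(v[order], q)
    return replace(cohort, scores=filled,
                   missing_mask=np.zeros_like(cohort.missing_mask),
                   node_labels=labels if k != cohort.k else cohort.node_labels,
                   latent=None)


# ---------------------------------------------------------------------------
# correlation matrices

def spearman_matrix(cohort: Cohort) -> CorrelationMatrix:
    """Pairwise-complete mid-rank Spearman correlation matrix.

    If the raw matrix is not positive semidefinite it is projected to the
    nearest PSD matrix (negative eigenvalues clipped, re-standardized) and
    the repair is flagged.
    """
    obs = cohort.observed()
    n, k = obs.shape
    for j in range(k):
        v = obs[:, j][~np.isnan(obs[:, j])]
        if v.size == 0 or v.max() == v.min():
            raise ValueError(
                f"column {cohort.node_labels[j]} is constant; Spearman "
                "correlation undefined")
    R = np.eye(k)
    neff = np.full((k, k), n, dtype=float)
    for i in range(k):
        for j in range(i + 1, k):
            both = ~np.isnan(obs[:, i]) & ~np.isnan(obs[:, j])
            m = int(both.sum())
            if m < 3:
                raise ValueError("fewer than 3 complete pairs for "
                                 f"({cohort.node_labels[i]}, {cohort.node_labels[j]})")
            r = stats.spearmanr(obs[both, i], obs[both, j]).statistic
            R[i, j] = R[j, i] = r
            neff[i, j] = neff[j, i] = m
    R, repaired = _psd_repair(R)
    return CorrelationMatrix(values=R, method="spearman", n_effective=neff,
                             node_labels=list(cohort.node_labels),
                             repaired=repaired)


def _polychoric_pair(xi: np.ndarray, xj: np.ndarray) -> float:
    """Two-step polychoric estimate for one pair of ordinal columns."""
    ci, ti = _thresholds(xi)
    cj, tj = _thresholds(xj)
    table = np.zeros((len(ci), len(cj)))
    for a, cat_i in enumerate(ci):
        sel = xi == cat_i
        for b, cat_j in enumerate(cj):
            table[a, b] = np.sum(sel & (xj == cat_j))
    ti = np.concatenate(([-np.inf], ti, [np.inf]))
    tj = np.concatenate(([-np.inf], tj, [np.inf]))
    a_lo, b_lo = np.meshgrid(ti[:-1], tj[:-1], indexing="ij")
    a_hi, b_hi = np.meshgrid(ti[1:], tj[1:], indexing="ij")

    def nll(rho):
        p = rect_prob(a_lo, a_hi, b_lo, b_hi, rho)
        return -np.sum(table * np.log(np.clip(p, 1e-300, None)))

    res = optimize.minimize_scalar(nll, bounds=(-0.999, 0.999),
                                   method="bounded",
                                   options={"xatol": 1e-6})
    return float(res.x)


def _thresholds(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    cats = np.unique(x)
    if len(cats) < 2:
        raise ValueError("margin with a single observed category")
    if len(cats) > 10:
        raise ValueError("more than 10 observed categories; not ordinal enough "
                         "for a polychoric model")
    props = np.array([(x == c).mean() for c in cats])
    cum = np.cumsum(props)[:-1]
    return cats, stats.norm.ppf(np.clip(cum, 1e-12, 1 - 1e-12))


def polychoric_matrix(cohort: Cohort) -> CorrelationMatrix:
    """Two-step polychoric correlation matrix for ordinal columns.

    Thresholds come from each margin's cumulative proportions; the pairwise
    latent correlation maximizes the bivariate-normal cell likelihood with a
    bounded scalar search on (-0.999, 0.999).
    """
    obs = cohort.observed()
    n, k = obs.shape
    R = np.eye(k)
    neff = np.full((k, k), n, dtype=float)
    for i in range(k):
        for j in range(i + 1, k):
            both = ~np.isnan(obs[:, i]) & ~np.isnan(obs[:, j])
            r = _polychoric_pair(obs[both, i], obs[both, j])
            R[i, j] = R[j, i] = r
            neff[i, j] = neff[j, i] = int(both.sum())
    R, repaired = _psd_repair(R)
    return CorrelationMatrix(values=R, method="polychoric", n_effective=neff,
                             node_labels=list(cohort.node_labels),
                             repaired=repaired)


def cronbach_alpha(corr: CorrelationMatrix, item_subset) -> float:
    """Standardized Cronbach's alpha from the mean inter-item correlation.

    ``alpha = k * rbar / (1 + (k - 1) * rbar)`` over the given item subset.
    """
    idx = [corr.node_labels.index(x) if isinstance(x, str) else int(x)
           for x in item_subset]
    k = len(idx)
    if k < 2:
        raise ValueError("alpha needs at least 2 items")
    sub = corr.values[np.ix_(idx, idx)]
    rbar = (sub.sum() - k) / (k * (k - 1))
    if rbar <= -1.0 / (k - 1):
        raise ValueError(f"mean inter-item correlation {rbar:.4f} <= -1/(k-1); "
                         "alpha undefined")
    return float(k * rbar / (1.0 + (k - 1) * rbar))


# ---------------------------------------------------------------------------
# on-disk formats

def write_correlation(corr: CorrelationMatrix, csv_path, sidecar_path=None) -> None:
    corr.to_frame().to_csv(csv_path)
    if sidecar_path is None:
        sidecar_path = str(csv_path) + ".json"
    with open(sidecar_path, "w") as fh:
        json.dump({"method": corr.method, "repaired": corr.repaired,
                   "n_effective": corr.n_effective.tolist()}, fh, indent=1)


def read_correlation(csv_path, sidecar_path=None) -> CorrelationMatrix:
    if sidecar_path is None:
        sidecar_path = str(csv_path) + ".json"
    df = pd.read_csv(csv_path, index_col=0)
    try:
        with open(sidecar_path) as fh:
            meta = json.load(fh)
    except FileNotFoundError:
        meta = {}
    values = df.to_numpy(dtype=float)
    neff = np.asarray(meta.get("n_effective",
                               np.full(values.shape, np.nan)), dtype=float)
    return CorrelationMatrix(values=values,
                             method=meta.get("method", "pearson"),
                             n_effective=neff,
                             node_labels=[str(c) for c in df.columns],
                             repaired=bool(meta.get("repaired", False)))
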