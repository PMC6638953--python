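"""Bivariate standard-normal CDF via Owen's T function.

Vectorized rectangle probabilities for the polychoric likelihood; handles
infinite limits and |rho| -> 1 degeneracies.
"""

from __future__ import annotations

import numpy as np
from scipy.special import owens_t
from scipy.stats import norm

__all__ = ["bvn_cdf", "rect_prob"]


def bvn_cdf(h, k, rho):
    """P(X <= h, Y <= k) for standard bivariate normal with correlation rho."""
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    h, k = np.broadcast_arrays(h, k)
    rho = float(rho)

    if abs(rho) >= 1.0 - 1e-12:
        if rho > 0:
            return norm.cdf(np.minimum(h, k))
        return np.maximum(norm.cdf(h) + norm.cdf(k) - 1.0, 0.0)

    out = np.empty(h.shape, dtype=float)

    hi_h = np.isposinf(h)
    hi_k = np.isposinf(k)
    lo = np.isneginf(h) | np.isneginf(k)
    out[lo] = 0.0
    out[hi_h & hi_k] = 1.0
    only_h = hi_h & ~hi_k & ~lo
    out[only_h] = norm.cdf(k[only_h])
    only_k = hi_k & ~hi_h & ~lo
    out[only_k] = norm.cdf(h[only_k])

    fin = ~(hi_h | hi_k | lo)
    # nudge exact-zero limits: the CDF is continuous in (h, k) while the
    # Owen decomposition has removable singularities at h = 0 / k = 0
    hf = np.where(h[fin] == 0.0, 1e-13, h[fin])
    kf = np.where(k[fin] == 0.0, 1e-13, k[fin])
    s = np.sqrt(1.0 - rho * rho)
    a1 = (kf - rho * hf) / (hf * s)
    a2 = (hf - rho * kf) / (kf * s)
    t1 = owens_t(hf, a1)
    t2 = owens_t(kf, a2)
    delta = np.where(hf * kf < 0.0, 0.5, 0.0)
    out[fin] = 0.5 * (norm.cdf(hf) + norm.cdf(kf)) - t1 - t2 - delta
    return np.clip(out, 0.0, 1.0)


def rect_prob(a_lo, a_hi, b_lo, b_hi, rho):
    """P(a_lo < X <= a_hi, b_lo < Y <= b_hi), vectorized over the limits."""
    p = (bvn_cdf(a_hi, b_hi, rho) - bvn_cdf(a_lo, b_hi, rho)
         - bvn_cdf(a_hi, b_lo, rho) + bvn_cdf(a_lo, b_lo, rho))
    return np.clip(p, 0.0, 1.0)
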