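"""Adaptive multiple-testing procedures and Z conversion.

The FWE adjustment is a step-down Holm procedure whose Bonferroni multiplier
is replaced by an estimate of the number of true null hypotheses; the FDR
adjustment is the analogous adaptive step-up variant of Benjamini-Hochberg.
The null count is estimated by an iterated least-squares fit of the upper
tail of the sorted p-values to the uniform order-statistic line.  Hommel's
method is provided for the small ROI-level test families.

All adjusters return adjusted p-values (never reject flags) in the original
order, are monotone, and are bounded by 1.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats

__all__ = [
    "estimate_m0_leastsquares",
    "holm_adaptive",
    "fdr_adaptive_stepup",
    "hommel_adjust",
    "p_to_z",
    "Z_FLOOR_P",
]

#: p-values are clamped at this value before Z conversion so maps stay finite.
Z_FLOOR_P = 1.0 - 1e-16


def _check_p(p) -> np.ndarray:
    p = np.asarray(p, dtype=float).ravel()
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return p


def estimate_m0_leastsquares(p, tail_fraction: float = 0.5,
                             max_iter: int = 100) -> float:
    """Least-squares estimate of the number of true null hypotheses.

    True-null p-values in the upper tail follow the order-statistic line
    ``p_(i) = 1 - (m - i) / m0``; the slope is fitted through the origin on
    ``(m - i, 1 - p_(i))`` over the largest p-values.  The fit is iterated:
    each new estimate restricts the tail to the top ``m0_hat`` p-values
    (never fewer than 2) until the estimate stabilises.  Result clipped to
    [0, m].
    """
    p = _check_p(p)
    m = p.size
    if m < 2:
        return float(m)
    ps = np.sort(p)
    if np.all(ps == ps[0]):
        warnings.warn("degenerate p-value vector; m0 set to m",
                      RuntimeWarning, stacklevel=2)
        return float(m)
    ranks = np.arange(1, m + 1)
    x_all = (m - ranks).astype(float)
    y_all = 1.0 - ps

    n_tail = max(int(np.ceil(tail_fraction * m)), 2)
    for _ in range(max_iter):
        x = x_all[m - n_tail:]
        y = y_all[m - n_tail:]
        sxy = float(x @ y)
        if sxy <= 0:
            m0 = 0.0
            break
        m0 = float(x @ x) / sxy
        n_new = int(np.clip(np.ceil(m0), 2, m))
        if n_new == n_tail:
            break
        n_tail = n_new
    return float(np.clip(m0, 0.0, m))


def holm_adaptive(p, m0_hat: float) -> np.ndarray:
    """Adaptive step-down (Holm-type) FWE-adjusted p-values.

    Sorted ascending, ``adj_(i) = max_{j<=i} min(1, max(m0 - j + 1, 1) *
    p_(j))``; classical Holm when ``m0_hat == m``.
    """
    p = _check_p(p)
    m = p.size
    if not 0 <= m0_hat <= m:
        raise ValueError("m0_hat must lie in [0, m]")
    order = np.argsort(p, kind="stable")
    ps = p[order]
    mult = np.maximum(m0_hat - np.arange(m), 1.0)
    adj = np.minimum(np.maximum.accumulate(mult * ps), 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def fdr_adaptive_stepup(p, m0_hat: float) -> np.ndarray:
    """Adaptive step-up (BH-type) FDR-adjusted p-values.

    ``adj_(i) = min_{j>=i} min(1, m0_hat * p_(j) / j)``; classical
    Benjamini-Hochberg when ``m0_hat == m``.  Adjusted values are floored
    at the raw p (the adaptive multiplier can otherwise drop below 1 for
    ranks beyond m0_hat).
    """
    p = _check_p(p)
    m = p.size
    if not 0 < m0_hat <= m:
        raise ValueError("m0_hat must lie in (0, m]")
    order = np.argsort(p, kind="stable")
    ps = p[order]
    raw = m0_hat * ps / np.arange(1, m + 1)
    adj = np.minimum(np.minimum.accumulate(raw[::-1])[::-1], 1.0)
    adj = np.maximum(adj, ps)
    out = np.empty(m)
    out[order] = adj
    return out


def hommel_adjust(p) -> np.ndarray:
    """Hommel (1988) adjusted p-values (valid under positive dependence)."""
    p = _check_p(p)
    n = p.size
    if n == 1:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ps = p[order]
    i = np.arange(1, n + 1)
    q = np.full(n, min((n * ps / i).min(), 1.0))
    pa = q.copy()
    for m in range(n - 1, 1, -1):
        i1 = np.arange(n - m + 1)
        i2 = np.arange(n - m + 1, n)
        q1 = (m * ps[i2] / np.arange(2, m + 1)).min()
        q[i1] = np.minimum(m * ps[i1], q1)
        q[i2] = q[n - m]
        pa = np.maximum(pa, q)
    adj = np.minimum(np.maximum(pa, ps), 1.0)
    out = np.empty(n)
    out[order] = adj
    return out


def p_to_z(p_adjusted) -> np.ndarray:
    """Convert (adjusted) p-values to standard-normal quantiles.

    ``z = Phi^{-1}(1 - p)``; p is clamped at ``Z_FLOOR_P`` so ``p == 1``
    maps to a finite floor (about -8.2) instead of -inf.
    """
    p = np.asarray(p_adjusted, dtype=float)
    if np.any(p <= 0):
        raise ValueError("p-values must be > 0")
    return stats.norm.isf(np.minimum(p, Z_FLOOR_P))
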