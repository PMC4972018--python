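"""Small statistical helpers for comparing weighted emission profiles."""

from __future__ import annotations

import numpy as np
from scipy.stats import distributions

__all__ = ["weighted_ks_2samp"]


def weighted_ks_2samp(x1, x2, w1=None, w2=None):
    """Two-sample Kolmogorov-Smirnov test for weighted samples.

    Compares the weighted empirical CDFs of ``x1`` and ``x2``; weights default
    to one.  The p-value uses the asymptotic Kolmogorov distribution with the
    effective sample sizes ``(sum w)^2 / sum w^2``, which reduces to the
    standard two-sample test for unit weights.

    Returns
    -------
    (statistic, p_value)
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    w1 = np.ones_like(x1) if w1 is None else np.asarray(w1, dtype=float)
    w2 = np.ones_like(x2) if w2 is None else np.asarray(w2, dtype=float)
    if np.any(w1 < 0) or np.any(w2 < 0):
        raise ValueError("weights must be non-negative")

    o1, o2 = np.argsort(x1), np.argsort(x2)
    x1, w1 = x1[o1], w1[o1]
    x2, w2 = x2[o2], w2[o2]
    grid = np.union1d(x1, x2)
    cdf1 = np.concatenate([[0.0], np.cumsum(w1)]) / w1.sum()
    cdf2 = np.concatenate([[0.0], np.cumsum(w2)]) / w2.sum()
    c1 = cdf1[np.searchsorted(x1, grid, side="right")]
    c2 = cdf2[np.searchsorted(x2, grid, side="right")]
    stat = float(np.max(np.abs(c1 - c2)))

    n1 = w1.sum() ** 2 / np.sum(w1**2)
    n2 = w2.sum() ** 2 / np.sum(w2**2)
    n_eff = n1 * n2 / (n1 + n2)
    p = float(distributions.kstwobign.sf(stat * np.sqrt(n_eff)))
    return stat, min(max(p, 0.0), 1.0)
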