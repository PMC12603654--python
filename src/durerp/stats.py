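"""Group-level inference on fitted coefficients.

Spline coefficient vectors are tested across subjects against the zero
vector with a one-sample Hotelling T² test — the multivariate analogue of
the one-sample t-test — per (channel-or-ROI, lag) cell, and the resulting
p-values are corrected across cells with the Benjamini–Yekutieli step-up
procedure, which controls the false discovery rate under arbitrary
dependence at the cost of a harmonic-sum inflation factor.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sstats


def hotelling_t2(data: np.ndarray, cell: str | None = None) -> dict:
    """One-sample Hotelling T² test of a (subjects × p) matrix against 0.

    Returns ``{"t2": ..., "f": ..., "p": ..., "df1": p, "df2": n - p}``
    with ``F = T² (n − p) / (p (n − 1))`` referred to an F(p, n−p)
    distribution.
    """
    X = np.atleast_2d(np.asarray(data, float))
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more subjects than coefficients (n={n}, p={p})"
                         + (f" in cell {cell}" if cell else ""))
    if not np.all(np.isfinite(X)):
        raise ValueError("missing values in coefficient matrix"
                         + (f" in cell {cell}" if cell else ""))
    xbar = X.mean(axis=0)
    if not np.any(xbar):
        # zero mean vector: T2 = 0 regardless of the covariance
        return {"t2": 0.0, "f": 0.0, "p": 1.0, "df1": p, "df2": n - p}
    S = np.cov(X, rowvar=False, ddof=1)
    S = np.atleast_2d(S)
    try:
        sol = np.linalg.solve(S, xbar)
    except np.linalg.LinAlgError as err:
        raise ValueError("singular sample covariance"
                         + (f" in cell {cell}" if cell else "")) from err
    t2 = float(n * xbar @ sol)
    f = t2 * (n - p) / (p * (n - 1))
    pval = float(sstats.f.sf(f, p, n - p))
    return {"t2": t2, "f": float(f), "p": pval, "df1": p, "df2": n - p}


def by_fdr(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini–Yekutieli adjusted p-values (step-up, c(m) = Σ 1/i).

    Output is monotone nondecreasing in the order of the sorted raw
    p-values and capped at 1.
    """
    p = np.asarray(pvalues, float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("pvalues must be a nonempty 1-D vector")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    c_m = np.sum(1.0 / np.arange(1, m + 1))
    order = np.argsort(p, kind="stable")
    ranked = p[order] * c_m * m / np.arange(1, m + 1)
    # step-up: running minimum from the largest rank downward
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def bh_fdr(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (c(m) = 1 variant of BY)."""
    p = np.asarray(pvalues, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum(np.minimum.accumulate(ranked[::-1])[::-1], 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def max_effect_ttest(differences: np.ndarray) -> dict:
    """One-sample t-test companion for maximal-marginal-effect differences.

    ``differences`` is subjects × cells (or 1-D); returns per-cell t
    statistics, raw p-values, and BY-adjusted p-values across cells.
    """
    D = np.atleast_2d(np.asarray(differences, float))
    res = sstats.ttest_1samp(D, 0.0, axis=0)
    praw = np.atleast_1d(res.pvalue)
    return {"t": np.atleast_1d(res.statistic), "p_raw": praw,
            "p_fdr": by_fdr(praw)}
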