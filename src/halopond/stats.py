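"""Correlation and multiple-testing primitives shared by the network and
CAZyme stages.

Pearson p-values come from the t-transform t = r*sqrt((n-2)/(1-r^2)) with
n-2 degrees of freedom, two-sided.  FDR control is Benjamini-Hochberg
step-up.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps


def pearson_correlation(x: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs Pearson r and two-sided p over the rows of ``x``.

    Rows are features (OTUs), columns are samples; all samples enter every
    pair (no pairwise deletion).  Zero-variance rows have undefined
    correlation and yield NaN r and p — no edge is possible for them.
    """
    n = x.shape[1]
    if n < 3:
        raise ValueError("need at least 3 samples for correlation p-values")
    arr = x.to_numpy(dtype=float)
    sd = arr.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(arr)
        r = np.clip(r, -1.0, 1.0)
    r[sd == 0, :] = np.nan
    r[:, sd == 0] = np.nan
    p = pearson_pvalue(r, n)
    idx = x.index
    return (
        pd.DataFrame(r, index=idx, columns=idx),
        pd.DataFrame(p, index=idx, columns=idx),
    )


def pearson_pvalue(r: np.ndarray | float, n: int) -> np.ndarray:
    """Two-sided p for Pearson r with n observations via the t-transform."""
    r = np.asarray(r, dtype=float)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r**2))
    p = 2.0 * sps.t.sf(np.abs(t), df)
    # |r| = 1 gives an infinite t statistic: the p-value is exactly 0
    p = np.where(np.isclose(np.abs(r), 1.0), 0.0, p)
    p = np.where(np.isnan(r), np.nan, p)
    return p


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j>=i} min(1, p_(j) * m / j) over the sorted p-values, with
    the original order restored.  Input must lie in [0, 1].
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    flat = p.ravel()
    m = flat.size
    order = np.argsort(flat, kind="mergesort")  # stable: ties keep input order
    ranked = flat[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(np.minimum.accumulate(ranked[::-1])[::-1], 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q.reshape(p.shape)
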