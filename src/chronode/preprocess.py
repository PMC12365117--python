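"""Replicate-level preprocessing: batch correction, positive shift, quantile
normalization, and polynomial time-course testing for dynamic features.

The input is a feature x (timepoint x replicate) matrix.  Batch effects
(replicate, and assay when DNase- and ATAC-seq tracks are harmonized into one
course) are removed by least squares jointly with the time design, so real
temporal trends are not absorbed into the batch terms.  Features changing
over time are then called by polynomial regression (degrees 1 and 2) with an
overall F-test per degree and Benjamini-Hochberg adjustment across features.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "remove_batch_effects",
    "shift_to_positive",
    "quantile_normalize",
    "bh_adjust",
    "polynomial_timecourse_test",
]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]


def _sum_to_zero_dummies(labels) -> np.ndarray:
    """Sum-to-zero (deviation) coding: L levels -> L-1 columns; the last
    level is coded -1 in every column, so batch terms average to zero."""
    labels = np.asarray(labels)
    levels = pd.unique(labels)
    if len(levels) < 2:
        return np.empty((len(labels), 0))
    cols = np.zeros((len(labels), len(levels) - 1))
    for j, lev in enumerate(levels[:-1]):
        cols[labels == lev, j] = 1.0
    cols[labels == levels[-1], :] = -1.0
    return cols


def remove_batch_effects(matrix, batch_factors, design) -> pd.DataFrame:
    """Subtract batch effects estimated jointly with the time design.

    Parameters
    ----------
    matrix : DataFrame, features x samples.
    batch_factors : one categorical vector or a list of one/two of them
        (e.g. replicate, assay), aligned with the columns.
    design : numeric time covariate per column (PC days).

    The model per feature is ``signal ~ 1 + time + batches`` with batches
    sum-to-zero coded; only the batch part is subtracted, so the grand mean
    and the temporal trend are preserved.  A batch factor confounded with
    the design (rank-deficient joint model) raises, naming the factor.
    """
    values = pd.DataFrame(matrix)
    design = np.asarray(design, dtype=float)
    if design.shape[0] != values.shape[1]:
        raise ValueError("design length must equal the number of columns")
    if not isinstance(batch_factors, (list, tuple)):
        batch_factors = [batch_factors]
    base = np.column_stack([np.ones_like(design), design])
    blocks, names = [], []
    for i, factor in enumerate(batch_factors):
        factor = np.asarray(factor)
        if factor.shape[0] != values.shape[1]:
            raise ValueError("every batch factor must label all columns")
        blocks.append(_sum_to_zero_dummies(factor))
        names.append(f"batch_factor_{i}")
    full = np.hstack([base] + blocks)
    rank_base = np.linalg.matrix_rank(base)
    for name, block in zip(names, blocks):
        joint = np.hstack([base, block])
        if np.linalg.matrix_rank(joint) < rank_base + block.shape[1]:
            raise ValueError(f"{name} is confounded with the time design")
    if np.linalg.matrix_rank(full) < full.shape[1]:
        raise ValueError("batch factors are mutually confounded")
    beta, *_ = np.linalg.lstsq(full, values.to_numpy().T, rcond=None)
    batch_part = np.hstack(blocks) @ beta[2:, :]
    corrected = values.to_numpy() - batch_part.T
    return pd.DataFrame(corrected, index=values.index, columns=values.columns)


def shift_to_positive(matrix):
    """Shift the whole matrix up by |global min| when the minimum is
    negative, preserving all pairwise differences; returns (matrix, shift)."""
    values = pd.DataFrame(matrix)
    arr = values.to_numpy()
    if not np.all(np.isfinite(arr)):
        raise ValueError("matrix contains non-finite values")
    gmin = arr.min()
    shift = float(abs(gmin)) if gmin < 0 else 0.0
    return values + shift, shift


def quantile_normalize(columns):
    """Joint quantile normalization: each column's sorted values are replaced
    by the across-column mean of sorted values, restored to original ranks.
    Tied values receive the average of the corresponding target means."""
    df = pd.DataFrame(columns)
    arr = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("columns contain non-finite values")
    target = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        order = np.argsort(arr[:, j], kind="mergesort")
        ranked = np.empty_like(target)
        ranked[order] = target
        # average target means across tied ranks
        out[:, j] = pd.Series(ranked).groupby(arr[:, j]).transform("mean").to_numpy()
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def _poly_f_test(y: np.ndarray, t: np.ndarray, degree: int) -> float:
    """Overall F-test p-value of a degree-d polynomial-in-time regression
    against the intercept-only model; p = 1 for an exactly constant series."""
    n = len(y)
    X = np.vander(t, degree + 1, increasing=True)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss1 = float(np.sum((y - X @ beta) ** 2))
    rss0 = float(np.sum((y - y.mean()) ** 2))
    df_num, df_den = degree, n - degree - 1
    if df_den <= 0:
        return np.nan
    if rss0 <= 1e-300:  # flat series: no variance to explain
        return 1.0
    if rss1 <= 1e-300:
        return 0.0
    f = ((rss0 - rss1) / df_num) / (rss1 / df_den)
    return float(stats.f.sf(f, df_num, df_den))


def polynomial_timecourse_test(
    matrix, times, alpha: float = 0.01, min_obs: int = 5, max_degree: int = 2
) -> pd.DataFrame:
    """Call dynamic features by polynomial time-course regression.

    For each feature, replicate observations are pooled and linear
    (degree 1) and quadratic (degree 2) models in time are tested against
    the intercept-only model with an overall F-test.  P-values are BH
    adjusted across features within each degree, and a feature is dynamic
    when its smallest adjusted p-value is below ``alpha``.  Features with
    fewer than ``min_obs`` finite observations are excluded (flagged, not
    an error).
    """
    values = pd.DataFrame(matrix)
    times = np.asarray(times, dtype=float)
    if times.shape[0] != values.shape[1]:
        raise ValueError("times length must equal the number of columns")
    degrees = list(range(1, max_degree + 1))
    pvals = {d: np.full(len(values), np.nan) for d in degrees}
    n_obs = np.zeros(len(values), dtype=int)
    for i, (_, row) in enumerate(values.iterrows()):
        y = row.to_numpy(dtype=float)
        finite = np.isfinite(y)
        n_obs[i] = int(finite.sum())
        if n_obs[i] < min_obs:
            continue
        for d in degrees:
            pvals[d][i] = _poly_f_test(y[finite], times[finite], d)
    out = pd.DataFrame({"feature_id": values.index, "n_obs": n_obs})
    out["excluded"] = n_obs < min_obs
    for d in degrees:
        name = {1: "linear", 2: "quadratic"}.get(d, f"deg{d}")
        out[f"p_{name}"] = pvals[d]
        adj = np.full(len(out), np.nan)
        tested = np.isfinite(pvals[d])
        if tested.any():
            adj[tested] = bh_adjust(pvals[d][tested])
        out[f"adj_p_{name}"] = adj
    adj_cols = [c for c in out.columns if c.startswith("adj_p_")]
    min_adj = out[adj_cols].min(axis=1)
    out["is_dynamic"] = (min_adj < alpha) & ~out["excluded"]
    return out.set_index("feature_id", drop=False)
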