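"""Matrix-level drivers tying the per-feature operations together."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ode import annotate, characteristic_times, classify_kinetics, cluster_quadrants, fit_best
from .piecewise import fit_piecewise

__all__ = ["fit_matrix", "piecewise_matrix"]


def fit_matrix(matrix: pd.DataFrame, t_end: float | None = None,
               quadrants: bool = True, quadrant_seed: int = 0):
    """Fit every row of a feature x timepoint matrix with the four-candidate
    logistic procedure and annotate kinetics.

    Returns (params, fitted): ``params`` has one row per feature in the
    stable output column order; ``fitted`` holds the reconstructed curves
    in the original units at the observed times (NaN rows for
    non-converged features).
    """
    times = np.asarray(matrix.columns, dtype=float)
    t_end = float(times[-1]) if t_end is None else t_end
    rows, fitted = [], []
    for fid, row in matrix.iterrows():
        fit = fit_best(row.to_numpy(dtype=float), times)
        if fit.converged:
            ann = annotate(fit, t_end)
            rows.append({
                "feature_id": fid, "converged": True, "range_used": fit.range_id,
                "k": fit.k, "b": fit.b, "a": fit.a, "mse": fit.mse,
                "direction": ann.direction, "t_switch": ann.t_switch,
                "t_minimum": ann.t_minimum, "t_saturation": ann.t_saturation,
                "kinetic_class": ann.kinetic_class, "quadrant": pd.NA,
            })
            fitted.append(fit.fitted_original)
        else:
            rows.append({"feature_id": fid, "converged": False,
                         "range_used": pd.NA, "k": np.nan, "b": np.nan,
                         "a": np.nan, "mse": np.nan, "direction": pd.NA,
                         "t_switch": np.nan, "t_minimum": np.nan,
                         "t_saturation": np.nan, "kinetic_class": pd.NA,
                         "quadrant": pd.NA})
            fitted.append(np.full(len(times), np.nan))
    params = pd.DataFrame(rows).set_index("feature_id", drop=False)
    conv = params["converged"].astype(bool)
    if quadrants and conv.sum() >= 3:
        pts = np.column_stack([params.loc[conv, "k"].abs(), params.loc[conv, "b"]])
        try:
            labels, _ = cluster_quadrants(pts, seed=quadrant_seed)
            params.loc[conv, "quadrant"] = labels
        except ValueError:
            pass  # too few distinct (|k|, b) points to cluster
    fitted_df = pd.DataFrame(fitted, index=matrix.index, columns=times)
    return params, fitted_df


def piecewise_matrix(matrix: pd.DataFrame, feature_ids=None):
    """Piecewise-fit selected rows (default: all).  Returns (params, fitted)
    with segment rates, the averaged |k|, and the spline-smoothed curves."""
    times = np.asarray(matrix.columns, dtype=float)
    sub = matrix if feature_ids is None else matrix.loc[list(feature_ids)]
    rows, fitted = [], []
    for fid, row in sub.iterrows():
        try:
            pw = fit_piecewise(row.to_numpy(dtype=float), times)
        except ValueError:
            pw = None
        if pw is not None and pw.converged:
            rows.append({"feature_id": fid, "converged": True,
                         "t_peak": pw.t_peak, "k_left": pw.k_left,
                         "k_right": pw.k_right, "k_avg": pw.k_avg,
                         "offset_right": pw.offset_right, "mse": pw.mse})
            fitted.append(pw.smoothed)
        else:
            rows.append({"feature_id": fid, "converged": False,
                         "t_peak": np.nan, "k_left": np.nan, "k_right": np.nan,
                         "k_avg": np.nan, "offset_right": np.nan, "mse": np.nan})
            fitted.append(np.full(len(times), np.nan))
    params = pd.DataFrame(rows).set_index("feature_id", drop=False)
    fitted_df = pd.DataFrame(fitted, index=sub.index, columns=times)
    return params, fitted_df
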