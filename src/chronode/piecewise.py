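"""Piecewise logistic fitting for peak- and valley-shaped profiles.

Profiles rejected by the monotonic triage are split at their global interior
extremum, each side is fitted with the standard four-candidate logistic
procedure, the right segment is vertically shifted so the two curves meet
exactly at the extremum (zero-order continuity), and the concatenated curve
is smoothed with an interpolating quadratic B-spline on a dense grid, whose
degree guarantees first-derivative continuity.  The segment rate constants
remain interpretable; the reported overall rate is their average magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import make_interp_spline

from .ode import LogisticFit, fit_best, reconstruct_original

__all__ = ["PiecewiseFit", "find_global_extremum", "fit_piecewise"]

#: points per segment (including the shared extremum) required for fitting
_MIN_SEG = 4
#: dense-grid resolution for the spline smoothing step
_GRID = 200


@dataclass
class PiecewiseFit:
    converged: bool
    t_peak: float = np.nan
    peak_index: int = -1
    left_fit: LogisticFit | None = None
    right_fit: LogisticFit | None = None
    offset_right: float = np.nan
    k_left: float = np.nan
    k_right: float = np.nan
    k_avg: float = np.nan
    smoothed: np.ndarray | None = None
    mse: float = np.nan


def find_global_extremum(z, times) -> int:
    """Index of the interior global extremum of a peak/valley profile.

    The global maximum is used when it is interior (peak shape); otherwise
    the global minimum (valley shape).  Equal extrema resolve to the
    earliest time point.  A boundary-only extremum means the series is
    monotonic-like and belongs to the monotonic pipeline.
    """
    z = np.asarray(z, dtype=float)
    if len(z) < 2 * _MIN_SEG - 1:
        raise ValueError(f"need at least {2 * _MIN_SEG - 1} points")
    i_max = int(np.argmax(z))  # argmax/argmin take the first of ties
    i_min = int(np.argmin(z))
    last = len(z) - 1
    if 0 < i_max < last:
        return i_max
    if 0 < i_min < last:
        return i_min
    raise ValueError("extremum at a boundary: monotonic; use monotonic fitting")


def _segment_curve(fit: LogisticFit, grid: np.ndarray) -> np.ndarray:
    z0 = float(fit.fitted_original[0])
    return reconstruct_original(grid, fit.k, fit.a, fit.b, z0, fit.t_start)


def fit_piecewise(z, times) -> PiecewiseFit:
    """Two-segment logistic fit joined at the global extremum.

    Both segments share the extremum point.  Segments are fitted freely;
    the right curve is then shifted by ``offset_right`` so the two analytic
    curves agree exactly at t_peak.  The concatenated curve, sampled on a
    200-point grid, is interpolated by a quadratic B-spline (C1 by
    construction) and evaluated at the observed times.  Either segment
    failing to converge, or a segment shorter than 4 points, yields a
    non-converged record.
    """
    z = np.asarray(z, dtype=float)
    times = np.asarray(times, dtype=float)
    idx = find_global_extremum(z, times)
    t_peak = float(times[idx])
    if idx + 1 < _MIN_SEG or len(z) - idx < _MIN_SEG:
        return PiecewiseFit(converged=False, t_peak=t_peak, peak_index=idx)
    left = fit_best(z[: idx + 1], times[: idx + 1])
    right = fit_best(z[idx:], times[idx:])
    if not (left.converged and right.converged):
        return PiecewiseFit(converged=False, t_peak=t_peak, peak_index=idx,
                            left_fit=left, right_fit=right)

    grid_left = np.linspace(times[0], t_peak, _GRID // 2)
    grid_right = np.linspace(t_peak, times[-1], _GRID // 2)
    curve_left = _segment_curve(left, grid_left)
    curve_right = _segment_curve(right, grid_right)
    offset = float(curve_left[-1] - curve_right[0])
    curve_right = curve_right + offset

    grid = np.concatenate([grid_left, grid_right[1:]])
    curve = np.concatenate([curve_left, curve_right[1:]])
    spline = make_interp_spline(grid, curve, k=2)
    smoothed = spline(times)
    mse = float(np.mean((smoothed - z) ** 2))
    k_l, k_r = float(left.k), float(right.k)
    return PiecewiseFit(
        converged=True, t_peak=t_peak, peak_index=idx,
        left_fit=left, right_fit=right, offset_right=offset,
        k_left=k_l, k_right=k_r, k_avg=(abs(k_l) + abs(k_r)) / 2.0,
        smoothed=np.asarray(smoothed), mse=mse,
    )
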