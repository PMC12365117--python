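"""Logistic-ODE kinetic modeling of monotonic time-series genomic signals.

A genomic signal z(t) (gene expression in log2 TPM, chromatin accessibility)
constrained to [a, b] and evolving cooperatively towards saturation obeys the
generalized logistic ODE

    dz/dt = k (z - a) (1 - (z - a)/(b - a)).

Fitting the three-parameter form directly is unstable on short series, so the
data are min-max normalized to a range where the lower asymptote can be pinned
at zero and the two-parameter simplified form

    dy*/dt = k* y* (1 - y*/b*),   y*(t_start) = y*_start

is fitted instead, via its closed-form solution.  The rate constant k is
invariant under the normalization; a and b are recovered by the inverse
min-max map.  Characteristic times (switch, minimum, saturation) and the
kinetic class (switcher / accelerator / decelerator) follow from (k*, b*,
y*_start) alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.special import expit, logit
from sklearn.cluster import KMeans

__all__ = [
    "RANGES",
    "NormalizedSeries",
    "LogisticFit",
    "KineticAnnotation",
    "minmax_normalize",
    "analytic_solution",
    "fit_simplified_ode",
    "fit_best",
    "inverse_transform_params",
    "reconstruct_original",
    "characteristic_times",
    "classify_kinetics",
    "cluster_quadrants",
]

#: Normalization target ranges.  "unit" ([1e-5, 1]) suits signals entered
#: through their acceleration phase; "shifted" is the unit range moved up by
#: one (~[1, 2]), accommodating series matching only the deceleration tail
#: of a logistic curve.
RANGES: dict[str, tuple[float, float]] = {
    "unit": (1e-5, 1.0),
    "shifted": (1.0 + 1e-5, 2.0),
}

#: Optimizer box constraints keeping candidates inside the logistic
#: parameter space: |k*| <= 50 per day, b* in (1e-6, 10].
K_BOUND = 50.0
B_UPPER = 10.0
B_LOWER = 1e-6


@dataclass
class NormalizedSeries:
    """A feature's series mapped onto one of the two normalization ranges."""

    y_star: np.ndarray
    times: np.ndarray
    range_id: str
    r_min: float
    r_max: float
    z_min: float
    z_max: float


@dataclass
class LogisticFit:
    """Fitted record of the simplified logistic ODE for one feature.

    Starred parameters live in the normalized range; ``a``, ``b`` and ``k``
    are in the original units of the data (k* == k).  ``converged`` is False
    for an "NA solution": the optimizer failed or left the logistic space,
    and all numeric fields are NaN.
    """

    converged: bool
    range_id: str | None = None
    k_star: float = np.nan
    b_star: float = np.nan
    a_star: float = 0.0
    k: float = np.nan
    a: float = np.nan
    b: float = np.nan
    C_star: float = np.nan
    y_start_star: float = np.nan
    t_start: float = np.nan
    mse: float = np.nan
    z_min: float = np.nan
    z_max: float = np.nan
    fitted_normalized: np.ndarray | None = None
    fitted_original: np.ndarray | None = None


@dataclass
class KineticAnnotation:
    """Direction, characteristic times and kinetic class of a converged fit."""

    direction: str  # "activated" (k > 0) or "repressed" (k < 0)
    t_switch: float
    t_minimum: float
    t_saturation: float
    kinetic_class: str  # switcher | accelerator | decelerator
    quadrant: str | None = None


def minmax_normalize(z, times, range_id: str = "unit") -> NormalizedSeries:
    """Min-max normalize a series onto ``RANGES[range_id]``.

    y* = (z - z_min)(R_max - R_min)/(z_max - z_min) + R_min.  The "shifted"
    range equals the "unit" range plus one.  Raises on constant input
    (z_max == z_min) since the map is degenerate there.
    """
    z = np.asarray(z, dtype=float)
    times = np.asarray(times, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("series contains non-finite values")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    z_min, z_max = float(z.min()), float(z.max())
    if z_max <= z_min:
        raise ValueError("degenerate series: z_max == z_min")
    r_min, r_max = RANGES[range_id]
    y_star = (z - z_min) * (r_max - r_min) / (z_max - z_min) + r_min
    return NormalizedSeries(y_star, times, range_id, r_min, r_max, z_min, z_max)


def _log_ratio(k_star, b_star, y_start_star, t_start, t):
    """log[(b*/y*_start - 1) e^{-k*(t - t_start)}], the log-odds deficit."""
    return np.log(b_star / y_start_star - 1.0) - k_star * (np.asarray(t, dtype=float) - t_start)


def analytic_solution(t, k_star, b_star, y_start_star, t_start):
    """Closed-form solution of the simplified logistic ODE.

    y*(t) = b* C* e^{k* t} / (b* + C* e^{k* t}) with
    C* = y*_start / ((1 - y*_start/b*) e^{k* t_start}); evaluated in the
    numerically stable sigmoid form b* / (1 + (b*/y*_start - 1)
    e^{-k*(t - t_start)}), which never overflows for large |k* t|.
    """
    if b_star <= 0:
        raise ValueError("b_star must be positive")
    if not 0.0 < y_start_star < b_star:
        raise ValueError("y_start_star must lie in (0, b_star) on the standard branch")
    y = b_star * expit(-_log_ratio(k_star, b_star, y_start_star, t_start, t))
    return y


def integration_constant(k_star, b_star, y_start_star, t_start) -> float:
    """C* of the closed-form solution, computed in log space to avoid overflow."""
    log_c = np.log(y_start_star) - np.log1p(-y_start_star / b_star) - k_star * t_start
    with np.errstate(over="ignore"):
        return float(np.exp(log_c))


def _candidate_curve(params, y0, t0, times):
    """Model curve during optimization; +inf residuals outside the branch."""
    k, b = params
    if b <= y0:
        return np.full_like(times, np.inf)
    return b * expit(-_log_ratio(k, b, y0, t0, times))


def fit_simplified_ode(
    series: NormalizedSeries,
    k_init: float = 0.9,
    b_init: float = 1.5,
    max_evals: int = 5000,
) -> LogisticFit:
    """Nonlinear least squares of the closed-form logistic solution.

    Optimizes (k*, b*) from the given initial guesses with y*_start fixed to
    the first observed value and t_start to the first time point, constrained
    to the logistic parameter space (b* > y*_start, |k*| <= 50).  A failure
    to converge is returned as a non-converged record, not raised.
    """
    y = series.y_star
    t = series.times
    if len(y) < 4:
        raise ValueError("need at least 4 time points")
    y0 = float(y[0])
    t0 = float(t[0])
    na = LogisticFit(converged=False, range_id=series.range_id,
                     z_min=series.z_min, z_max=series.z_max,
                     y_start_star=y0, t_start=t0)
    if not 0.0 < y0:
        return na
    b_lo = max(B_LOWER, y0 * (1.0 + 1e-9))
    if b_lo >= B_UPPER:
        return na
    # each initial guess explores its own sign half-space, |k*| in (1e-6, 50]
    if k_init == 0:
        raise ValueError("k_init must be nonzero")
    k_bounds = (1e-6, K_BOUND) if k_init > 0 else (-K_BOUND, -1e-6)
    x0 = np.array([np.clip(k_init, *k_bounds),
                   np.clip(b_init, b_lo * (1 + 1e-6) + 1e-12, B_UPPER)])

    def resid(p):
        return _candidate_curve(p, y0, t0, t) - y

    try:
        res = least_squares(
            resid, x0, bounds=([k_bounds[0], b_lo], [k_bounds[1], B_UPPER]),
            max_nfev=max_evals, method="trf",
        )
    except (ValueError, FloatingPointError):
        return na
    k_star, b_star = res.x
    fitted = _candidate_curve(res.x, y0, t0, t)
    if not (res.success and b_star > 0 and np.all(np.isfinite(fitted))):
        return na
    mse = float(np.mean((fitted - y) ** 2))
    a, b = inverse_transform_params(0.0, b_star, series.range_id,
                                    series.z_min, series.z_max)
    r_min, r_max = RANGES[series.range_id]
    fitted_orig = (fitted - r_min) * (series.z_max - series.z_min) / (r_max - r_min) + series.z_min
    return LogisticFit(
        converged=True, range_id=series.range_id,
        k_star=float(k_star), b_star=float(b_star), a_star=0.0,
        k=float(k_star), a=a, b=b,
        C_star=integration_constant(k_star, b_star, y0, t0),
        y_start_star=y0, t_start=t0, mse=mse,
        z_min=series.z_min, z_max=series.z_max,
        fitted_normalized=fitted, fitted_original=fitted_orig,
    )


#: Deterministic candidate order; also the tie-break order on equal MSE
#: (unit range before shifted, positive k_init before negative).
CANDIDATE_ORDER: tuple[tuple[str, float], ...] = (
    ("unit", 0.9), ("unit", -0.9), ("shifted", 0.9), ("shifted", -0.9),
)


def fit_best(z, times, k_init_mag: float = 0.9, b_init: float = 1.5,
             max_evals: int = 5000) -> LogisticFit:
    """Fit all four (k-init sign x normalization range) candidates, keep the
    converged candidate with the lowest normalized-space MSE.

    Returns a non-converged record when no candidate converges, or when the
    input series is constant (degenerate normalization).
    """
    candidates: list[LogisticFit] = []
    for range_id, k0 in CANDIDATE_ORDER:
        try:
            series = minmax_normalize(z, times, range_id)
        except ValueError:
            return LogisticFit(converged=False)
        fit = fit_simplified_ode(series, k_init=np.sign(k0) * abs(k_init_mag),
                                 b_init=b_init, max_evals=max_evals)
        if fit.converged and fit.b_star > 0:
            candidates.append(fit)
    if not candidates:
        return LogisticFit(converged=False)
    best = min(candidates, key=lambda f: f.mse)  # stable: first minimum wins
    return best


def inverse_transform_params(a_star, b_star, range_id, z_min, z_max):
    """Map normalized asymptotes (a*, b*) back to the original data units.

    a = (a* - R_min)(z_max - z_min)/(R_max - R_min) + z_min, likewise for b;
    k is unchanged between the two spaces.
    """
    r_min, r_max = RANGES[range_id]
    scale = (z_max - z_min) / (r_max - r_min)
    a = (a_star - r_min) * scale + z_min
    b = (b_star - r_min) * scale + z_min
    return float(a), float(b)


def reconstruct_original(t, k, a, b, z_start, t_start):
    """Generalized-logistic curve z(t) = (b-a) C e^{kt} / (1 + C e^{kt}) + a
    with C fixed by z(t_start) = z_start; stable sigmoid evaluation."""
    if b <= a:
        raise ValueError("require b > a")
    p0 = (z_start - a) / (b - a)
    if not 0.0 < p0 < 1.0:
        raise ValueError("z_start must lie strictly inside (a, b)")
    t = np.asarray(t, dtype=float)
    return a + (b - a) * expit(logit(p0) + k * (t - t_start))


def characteristic_times(k_star, b_star, y_start_star, t_start):
    """Characteristic times of the fitted curve, in days.

    t_switch    = (1/k*) ln(b*/y*_start - 1) + t_start      (inflection)
    t_minimum   = (1/k*) ln(1e-16 b*/y*_start) + t_start    (near-zero point)
    t_saturation= (1/k*) ln(99 b*/y*_start - 99) + t_start  (99% of b*)

    When a log argument is non-positive the time is undefined for that curve:
    t_switch gets a -inf sentinel (the inflection precedes any observable
    time; such fits classify as decelerators), t_saturation gets NaN.
    """
    if k_star == 0:
        raise ValueError("k_star must be nonzero")
    ratio = b_star / y_start_star
    arg_switch = ratio - 1.0
    t_switch = t_start + np.log(arg_switch) / k_star if arg_switch > 0 else -np.inf
    t_minimum = t_start + np.log(1e-16 * ratio) / k_star
    arg_sat = 99.0 * ratio - 99.0
    t_saturation = t_start + np.log(arg_sat) / k_star if arg_sat > 0 else np.nan
    return float(t_switch), float(t_minimum), float(t_saturation)


def classify_kinetics(t_switch, t_start, t_end) -> str:
    """Kinetic class from the position of t_switch in [t_start, t_end]:
    inside -> switcher, after -> accelerator, before -> decelerator."""
    if not t_start < t_end:
        raise ValueError("require t_start < t_end")
    if t_start <= t_switch <= t_end:
        return "switcher"
    if t_switch > t_end:
        return "accelerator"
    return "decelerator"


def annotate(fit: LogisticFit, t_end: float) -> KineticAnnotation:
    """Direction, characteristic times and kinetic class for a converged fit."""
    if not fit.converged:
        raise ValueError("cannot annotate a non-converged fit")
    direction = "activated" if fit.k_star > 0 else "repressed"
    ts, tm, tsat = characteristic_times(fit.k_star, fit.b_star,
                                        fit.y_start_star, fit.t_start)
    klass = classify_kinetics(ts, fit.t_start, t_end)
    return KineticAnnotation(direction, ts, tm, tsat, klass)


def cluster_quadrants(points, n_clusters: int = 3, seed: int = 0):
    """k-means grouping of (|k|, b) combinations into quadrant regions.

    Points are standardized and clustered with K=3 (configurable); clusters
    are labeled geometrically from their centroids: Q3 = highest saturation
    b, then Q1 = highest rate |k| among the rest, Q2 = the remainder (with
    K=4 the leftover high-rate/high-saturation centroid is Q4).  Returns
    (labels, info) where info holds the centroids (original units) and a
    ``q4_empty`` flag: True when no centroid lies in the high-|k|, high-b
    region, the regime the balance between rate and saturation forbids.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of (|k|, b)")
    if len(np.unique(pts, axis=0)) < n_clusters:
        raise ValueError("need at least n_clusters distinct points")
    mu = pts.mean(axis=0)
    sd = pts.std(axis=0)
    sd[sd == 0] = 1.0
    std = (pts - mu) / sd
    km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed).fit(std)
    centroids = km.cluster_centers_ * sd + mu
    order: dict[int, str] = {}
    remaining = list(range(n_clusters))
    i_q3 = max(remaining, key=lambda i: centroids[i, 1])
    order[i_q3] = "Q3"
    remaining.remove(i_q3)
    i_q1 = max(remaining, key=lambda i: centroids[i, 0])
    order[i_q1] = "Q1"
    remaining.remove(i_q1)
    if remaining:
        i_q2 = min(remaining, key=lambda i: centroids[i, 0])
        order[i_q2] = "Q2"
        remaining.remove(i_q2)
    for i in remaining:
        order[i] = "Q4"
    labels = np.array([order[c] for c in km.labels_])
    k_mid = (centroids[:, 0].min() + centroids[:, 0].max()) / 2.0
    b_mid = (centroids[:, 1].min() + centroids[:, 1].max()) / 2.0
    q4_empty = not any((c[0] > k_mid) and (c[1] > b_mid) for c in centroids)
    info = {"centroids": centroids, "centroid_labels": order, "q4_empty": q4_empty}
    return labels, info
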