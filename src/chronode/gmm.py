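"""Fit-quality triage: a two-component Gaussian mixture on per-feature MSEs.

Across a genome-wide run, the distribution of fit MSEs is bimodal: a tight
low-MSE component of acceptable fits and a broad high-MSE component of
profiles the monotonic logistic cannot describe (typically peak-shaped).
EM separates the two and the acceptability threshold is the equal-posterior
cut point between the component means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm
from sklearn.cluster import KMeans

__all__ = ["GmmPartition", "fit_gmm2", "equal_posterior_cutpoint"]

_MIN_WEIGHT = 1e-3
_MIN_SD = 1e-12


@dataclass
class GmmPartition:
    means: np.ndarray        # ordered: means[0] < means[1]
    sds: np.ndarray
    weights: np.ndarray
    cutpoint: float
    labels: np.ndarray       # "acceptable" | "unacceptable" per input value
    loglik: float
    loglik_trace: np.ndarray


def _mixture_loglik(x, w, mu, sd):
    comp = np.stack([np.log(w[j]) + norm.logpdf(x, mu[j], sd[j]) for j in range(2)])
    m = comp.max(axis=0)
    return float(np.sum(m + np.log(np.exp(comp - m).sum(axis=0))))


def fit_gmm2(mse_values, tol: float = 1e-8, max_iter: int = 1000,
             seed: int = 0) -> GmmPartition:
    """EM for a two-component univariate Gaussian mixture on MSE values.

    Initialized deterministically by 2-means on the values; iterates until
    the log-likelihood improves by less than ``tol`` or ``max_iter`` is hit.
    The cutpoint is the equal-posterior-responsibility point between the two
    component means (located by root finding; when several density crossings
    exist only the one between the means is used).  Values above the
    cutpoint are labeled unacceptable.

    Raises when the input is (near) constant or a component collapses
    (weight < 1e-3 or sd < 1e-12), which signals a unimodal MSE
    distribution for which a two-component triage is not meaningful.
    """
    x = np.asarray(mse_values, dtype=float)
    if x.ndim != 1 or len(x) < 20:
        raise ValueError("need at least 20 MSE values")
    if not np.all(np.isfinite(x)) or np.any(x < 0):
        raise ValueError("MSE values must be finite and non-negative")
    if np.var(x) <= 0:
        raise ValueError("zero-variance MSE values: nothing to partition")

    km = KMeans(n_clusters=2, n_init=10, random_state=seed).fit(x[:, None])
    mu = np.sort(km.cluster_centers_.ravel())
    assign = x > mu.mean()
    sd = np.array([
        x[~assign].std() if (~assign).any() else x.std(),
        x[assign].std() if assign.any() else x.std(),
    ])
    sd = np.maximum(sd, 1e-6 * x.std())
    w = np.array([(~assign).mean(), assign.mean()])
    w = np.clip(w, 1e-3, None)
    w = w / w.sum()

    trace = []
    prev = -np.inf
    for _ in range(max_iter):
        # E step
        logp = np.stack([np.log(w[j]) + norm.logpdf(x, mu[j], sd[j]) for j in range(2)])
        m = logp.max(axis=0)
        log_total = m + np.log(np.exp(logp - m).sum(axis=0))
        resp = np.exp(logp - log_total)
        ll = float(log_total.sum())
        if trace and ll < trace[-1] - 1e-9:
            raise AssertionError("EM log-likelihood decreased")
        trace.append(ll)
        if ll - prev < tol:
            break
        prev = ll
        # M step
        nk = resp.sum(axis=1)
        if np.any(nk / len(x) < _MIN_WEIGHT):
            raise ValueError("mixture component collapsed (weight < 1e-3); "
                             "the MSE distribution may be unimodal")
        w = nk / len(x)
        mu = (resp * x).sum(axis=1) / nk
        sd = np.sqrt((resp * (x - mu[:, None]) ** 2).sum(axis=1) / nk)
        if np.any(sd < _MIN_SD):
            raise ValueError("mixture component collapsed (sd < 1e-12); "
                             "the MSE distribution may be unimodal")

    order = np.argsort(mu)
    mu, sd, w = mu[order], sd[order], w[order]
    cut = equal_posterior_cutpoint(mu, sd, w)
    labels = np.where(x > cut, "unacceptable", "acceptable")
    return GmmPartition(mu, sd, w, cut, labels, trace[-1], np.asarray(trace))


def equal_posterior_cutpoint(means, sds, weights) -> float:
    """The point between the two component means where the posterior
    responsibilities are equal (for equal weights and sds this is exactly
    the midpoint of the means).  When the weighted densities have several
    crossings, only the one between the means is used."""
    mu = np.asarray(means, dtype=float)
    sd = np.asarray(sds, dtype=float)
    w = np.asarray(weights, dtype=float)

    def post_diff(v):
        return (np.log(w[0]) + norm.logpdf(v, mu[0], sd[0])
                - np.log(w[1]) - norm.logpdf(v, mu[1], sd[1]))

    lo, hi = float(mu[0]), float(mu[1])
    if lo == hi:
        return lo
    if post_diff(lo) * post_diff(hi) > 0:
        raise ValueError("no equal-posterior crossing between the component "
                         "means; components are not separable")
    return float(brentq(post_diff, lo, hi, xtol=1e-12))
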