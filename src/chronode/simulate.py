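"""Synthetic data generators with known ground truth.

Three generators emulate the data regimes the framework targets:

* ``simulate_logistic_matrix`` — monotone logistic trajectories over the
  8-point developmental grid (PC days 10.5-16.5 daily, then 21 for the
  postnatal point).  By default each row is generated as a fixed point of
  the min-max normalization the fitter applies (the observed series spans
  its normalization range exactly and starts at the pinned range end), so
  at zero noise the fitted parameters recover the generating ones almost
  exactly; passing ``y_start_range`` instead draws the starting level
  freely, producing partial-curve regimes (e.g. pure deceleration tails)
  without a round-trip guarantee.
* ``simulate_peak_matrix`` — two logistic segments joined continuously at
  an interior extremum, the profile shape the monotonic fit rejects.
* ``simulate_regulome`` — genes and cCREs on synthetic chromosomes with
  enhancer-like (positively contributing, same trajectory direction as the
  gene) and silencer-like (negatively contributing, opposite direction)
  accessibility tracks; gene expression is a weighted sum of its cCRE
  tracks plus noise.  The monotone construction guarantees the sign of
  every pair correlation at zero noise.

All generators are pure functions of their ``SimulationSpec`` (seed
included): identical specs give bitwise-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ode import RANGES, analytic_solution

__all__ = [
    "SimulationSpec",
    "DEFAULT_TIMES",
    "simulate_logistic_matrix",
    "simulate_peak_matrix",
    "simulate_regulome",
]

DEFAULT_TIMES = (10.5, 11.5, 12.5, 13.5, 14.5, 15.5, 16.5, 21.0)


@dataclass
class SimulationSpec:
    seed: int
    n_features: int = 100
    times: tuple = DEFAULT_TIMES
    k_range: tuple = (0.3, 1.5)          # |k| per day; >= 0.08 required
    b_range: tuple = (0.8, 2.0)          # free mode / peak segments only
    y_start_range: tuple | None = None   # fraction of b*; None = pinned mode
    noise_sd_fraction: float = 0.02      # Gaussian noise sd as fraction of range
    # regulome fields
    n_genes: int = 50
    ccres_per_gene: tuple = (1, 6)       # inclusive integer range
    enhancer_fraction: float = 0.66
    activated_fraction: float = 0.6      # probability a gene's direction is up
    genome_length: int = 20_000_000
    chrom_count: int = 2

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.noise_sd_fraction < 0:
            raise ValueError("noise_sd_fraction must be >= 0")
        times = np.asarray(self.times, dtype=float)
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.k_range[0] < 0.08:
            raise ValueError("k_range magnitudes below 0.08/day cannot "
                             "traverse the normalization range in this window")


def _pinned_values(k_signed: float, times: np.ndarray, range_id: str):
    """A logistic curve that exactly spans its normalization range.

    The first observed value sits at the pinned end of the range (the low
    end for increasing curves, the high end for decreasing ones) and the
    last at the opposite end, which ties b* to k:
    b* = R_min R_max (E - 1) / (R_min E - R_max), E = e^{|k| (t_end-t_start)}.
    Returns (values, b_star, y_start_star); raises when the rate is too
    slow to traverse the range in the window (E <= R_max/R_min).
    """
    rm, rM = RANGES[range_id]
    E = np.exp(abs(k_signed) * (times[-1] - times[0]))
    if rm * E <= rM * 1.0001:
        raise ValueError("rate too slow to traverse the range in this window")
    b = rm * rM * (E - 1) / (rm * E - rM)
    y0 = rm if k_signed > 0 else rM
    y = analytic_solution(times, k_signed, b, y0, times[0])
    return y, float(b), float(y0)


def _pinned_curve(rng, k_abs: float, sign: int, times: np.ndarray):
    """Draw a normalization-consistent curve; fast rates (able to traverse
    the unit range with b* within the fitter's bound) may use either range,
    slower rates use the shifted range."""
    T = times[-1] - times[0]
    full_possible = np.exp(k_abs * T) > 1.13e5  # also keeps b* <= 10
    use_unit = full_possible and rng.random() < 0.5
    range_id = "unit" if use_unit else "shifted"
    y, b, y0 = _pinned_values(sign * k_abs, times, range_id)
    return y, range_id, b, y0


def simulate_logistic_matrix(spec: SimulationSpec):
    """Generate monotone logistic rows with a ground-truth table.

    Returns (matrix, truth): ``matrix`` is features x times in original
    units; ``truth`` records per row the generating k, the asymptotes a
    and b mapped to the original units, y*_start, the true switching time
    and the direction.
    """
    rng = np.random.default_rng(spec.seed)
    times = np.asarray(spec.times, dtype=float)
    rows, truth = [], []
    for i in range(spec.n_features):
        sign = 1 if rng.random() < 0.5 else -1
        k_abs = rng.uniform(*spec.k_range)
        if spec.y_start_range is None:
            y, range_id, b_star, y0 = _pinned_curve(rng, k_abs, sign, times)
            r_min, r_max = RANGES[range_id]
        else:
            b_star = rng.uniform(*spec.b_range)
            frac = rng.uniform(*spec.y_start_range)
            y0 = frac * b_star
            y = analytic_solution(times, sign * k_abs, b_star, y0, times[0])
            range_id = "free"
            r_min, r_max = float(y.min()), float(y.max())
        lo = rng.uniform(0.5, 3.0)
        span = rng.uniform(1.0, 5.0)
        scale = span / (r_max - r_min)
        z = lo + (y - r_min) * scale
        a_orig = lo + (0.0 - r_min) * scale
        b_orig = lo + (b_star - r_min) * scale
        arg = b_star / y0 - 1.0
        t_switch = (times[0] + np.log(arg) / (sign * k_abs)) if arg > 0 else -np.inf
        z_noisy = z + rng.normal(0.0, spec.noise_sd_fraction * span, size=len(times))
        rows.append(z_noisy)
        truth.append({
            "feature_id": f"f{i:04d}", "k": sign * k_abs, "a": a_orig,
            "b": b_orig, "b_star": b_star, "y_start_star": y0,
            "range_id": range_id, "t_switch": float(t_switch),
            "direction": "activated" if sign > 0 else "repressed",
        })
    matrix = pd.DataFrame(rows, index=[t["feature_id"] for t in truth], columns=times)
    return matrix, pd.DataFrame(truth).set_index("feature_id", drop=False)


def simulate_peak_matrix(spec: SimulationSpec, valley_fraction: float = 0.0):
    """Peak- (or valley-) shaped rows: two logistic segments, continuous at
    a drawn interior extremum; truth records the segment rates and signs."""
    rng = np.random.default_rng(spec.seed)
    times = np.asarray(spec.times, dtype=float)
    n = len(times)
    if n < 7:
        raise ValueError("need at least 7 time points for peak shapes")
    rows, truth = [], []
    for i in range(spec.n_features):
        valley = rng.random() < valley_fraction
        idx = int(rng.integers(3, n - 3))       # both segments keep >= 4 points
        # segment rates fast enough to traverse their sub-window ranges
        t_left, t_right = times[: idx + 1], times[idx:]
        k_l = rng.uniform(max(spec.k_range[0], 2.4 / (t_left[-1] - t_left[0])),
                          spec.k_range[1] + 1.0)
        k_r = rng.uniform(max(spec.k_range[0], 2.4 / (t_right[-1] - t_right[0])),
                          spec.k_range[1])
        yl, _, _ = _pinned_values(+k_l, t_left, "shifted")
        yr, _, _ = _pinned_values(-k_r, t_right, "shifted")
        peak = rng.uniform(3.0, 6.0)
        amp_l = rng.uniform(1.0, 3.0)
        amp_r = rng.uniform(1.0, 3.0)
        left = peak - amp_l + (yl - yl.min()) * amp_l / np.ptp(yl)
        right = peak - amp_r + (yr - yr.min()) * amp_r / np.ptp(yr)
        z = np.concatenate([left, right[1:]])
        if valley:
            z = (z.max() + z.min()) - z
        rng_span = float(z.max() - z.min())
        z = z + rng.normal(0.0, spec.noise_sd_fraction * rng_span, size=n)
        rows.append(z)
        truth.append({
            "feature_id": f"p{i:04d}", "peak_index": idx, "t_peak": times[idx],
            "k_left": (-k_l if valley else k_l), "k_right": (k_r if valley else -k_r),
            "shape": "valley" if valley else "peak",
        })
    matrix = pd.DataFrame(rows, index=[t["feature_id"] for t in truth], columns=times)
    return matrix, pd.DataFrame(truth).set_index("feature_id", drop=False)


def _monotone_track(rng, direction: int, times: np.ndarray) -> np.ndarray:
    """A smooth monotone accessibility track with its own rate and scale."""
    k = rng.uniform(0.2, 1.2)
    b = 1.0
    y0 = 0.05 if direction > 0 else 0.85
    y = analytic_solution(times, direction * k, b, y0 * b, times[0])
    return rng.uniform(1.0, 3.0) * y + rng.uniform(0.5, 2.0)


def simulate_regulome(spec: SimulationSpec):
    """Genes, cCREs, coordinates and trajectories with linked ground truth.

    Genes are spaced >= 200 kb apart on ``chrom_count`` chromosomes with
    random strands; each gene's cCREs scatter within +/- 80 kb of it, so
    the generating gene is provably its nearest.  Per gene a trajectory
    direction is drawn; enhancer cCREs (probability ``enhancer_fraction``)
    share that direction and contribute positively to expression, silencer
    cCREs run opposite and contribute negatively, making every
    contribution monotone in the gene's direction — hence at zero noise
    enhancer pairs correlate positively and silencer pairs negatively by
    construction.  Returns (ccre_matrix, gene_matrix, ccre_bed, gene_bed,
    truth_links, truth_genes).
    """
    rng = np.random.default_rng(spec.seed)
    times = np.asarray(spec.times, dtype=float)
    spacing = 200_000
    per_chrom = int(np.ceil(spec.n_genes / spec.chrom_count))
    if per_chrom * spacing + 100_000 > spec.genome_length:
        raise ValueError("genome_length too small for the requested gene count")
    gene_rows, ccre_rows = [], []
    gene_traj, ccre_traj = {}, {}
    links, gene_truth = [], []
    for gi in range(spec.n_genes):
        chrom = f"chr{gi % spec.chrom_count + 1}"
        slot = gi // spec.chrom_count
        g_start = 100_000 + slot * spacing + int(rng.integers(0, 20_000))
        g_len = int(rng.integers(2_000, 20_000))
        strand = "+" if rng.random() < 0.5 else "-"
        gene_id = f"gene{gi:04d}"
        gene_rows.append({"chrom": chrom, "start": g_start, "end": g_start + g_len,
                          "id": gene_id, "score": 0, "strand": strand})
        direction = 1 if rng.random() < spec.activated_fraction else -1
        n_cc = int(rng.integers(spec.ccres_per_gene[0], spec.ccres_per_gene[1] + 1))
        contribs = np.zeros(len(times))
        gene_link_rows = []
        n_enh = 0
        for ci in range(n_cc):
            ccre_id = f"{gene_id}_ccre{ci}"
            offset = int(rng.integers(-80_000, 80_000))
            c_start = max(0, g_start + offset)
            c_len = int(rng.integers(200, 1_000))
            ccre_rows.append({"chrom": chrom, "start": c_start,
                              "end": c_start + c_len, "id": ccre_id,
                              "score": 0, "strand": "."})
            is_enh = rng.random() < spec.enhancer_fraction
            n_enh += is_enh
            track_dir = direction if is_enh else -direction
            track = _monotone_track(rng, track_dir, times)
            ccre_traj[ccre_id] = track
            w = rng.uniform(0.4, 1.0) / n_cc
            contribs = contribs + (w if is_enh else -w) * track
            gene_link_rows.append({
                "ccre_id": ccre_id, "gene_id": gene_id,
                "sign": "enhancer-like" if is_enh else "silencer-like",
                "k_sign": track_dir,
            })
        baseline = 1.0 - min(0.0, contribs.min())
        g = baseline + contribs
        g = g + rng.normal(0.0, spec.noise_sd_fraction * max(np.ptp(g), 1e-12),
                           size=len(times))
        gene_traj[gene_id] = g
        k_signs = {r["k_sign"] for r in gene_link_rows}
        pattern = "mono" if len(k_signs) == 1 else "poly"
        side = "enhancer" if n_enh > n_cc - n_enh else (
            "silencer" if n_enh < n_cc - n_enh else "tie")
        links.extend(gene_link_rows)
        gene_truth.append({"gene_id": gene_id, "n_ccres": n_cc,
                           "pattern": pattern, "side": side,
                           "direction": "activated" if direction > 0 else "repressed"})
    gene_bed = pd.DataFrame(gene_rows)
    ccre_bed = pd.DataFrame(ccre_rows)
    truth_links = pd.DataFrame(links)
    # brute-force nearest-gene distance for every cCRE, as generator truth
    dists = []
    for _, c in ccre_bed.iterrows():
        sub = gene_bed[gene_bed["chrom"] == c["chrom"]]
        d = np.maximum(0, np.maximum(sub["start"].to_numpy() - c["end"],
                                     c["start"] - sub["end"].to_numpy()))
        dists.append(int(d.min()))
    truth_links["distance_bp"] = dists
    gene_matrix = pd.DataFrame(gene_traj, index=times).T
    ccre_matrix = pd.DataFrame(ccre_traj, index=times).T
    return (ccre_matrix, gene_matrix, ccre_bed, gene_bed,
            truth_links, pd.DataFrame(gene_truth).set_index("gene_id", drop=False))
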