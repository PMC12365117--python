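"""cCRE-gene linking, regulatory-pattern classification, and the
count-versus-diversity interaction model.

Every candidate cis-regulatory element (cCRE) is assigned its nearest gene
by linear genomic distance (BED semantics, 0-based half-open).  Per pair,
the Pearson correlation between the fitted accessibility and expression
trajectories gives the regulatory sign: enhancer-like (r > 0) or
silencer-like (r < 0).  Genes whose linked cCREs all share one k-sign are
mono-pattern; mixed signs make a gene poly-pattern.  A logistic (or linear)
interaction model then disentangles the contribution of cCRE count and
pattern diversity to a gene-level response such as term membership or
expression fold-change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.outliers_influence import variance_inflation_factor
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

__all__ = [
    "GenePatternRecord",
    "nearest_gene",
    "tss_distance",
    "correlation_sign",
    "classify_pattern",
    "build_link_table",
    "fit_interaction_model",
    "hypergeometric_enrichment",
]

BED_COLUMNS = ["chrom", "start", "end", "id", "score", "strand"]


@dataclass
class GenePatternRecord:
    gene_id: str
    n_ccres: int
    pattern: str          # "mono" | "poly"
    group: str | None     # e.g. "enhancer-mono"; None when the sign vote ties
    fold_change: float
    sign_tie: bool = False


def _gap(s1, e1, s2, e2):
    """Gap in bp between half-open intervals [s1,e1) and [s2,e2); 0 if they
    overlap or touch base-adjacently is not counted as overlap (gap >= 1)."""
    return np.maximum(0, np.maximum(s2 - e1, s1 - e2))


def nearest_gene(ccres: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Assign each cCRE its closest gene by linear (gap) distance.

    Both inputs need columns chrom/start/end/id.  Overlap counts as
    distance 0.  Ties resolve deterministically to the leftmost gene
    (smallest start, then end, then lexicographic id); all tied genes are
    reported in a ``ties`` column.  cCREs on chromosomes without genes are
    returned unlinked (gene_id NA, flagged).
    """
    out_rows = []
    genes_by_chrom = {c: g.reset_index(drop=True) for c, g in genes.groupby("chrom")}
    for _, c in ccres.iterrows():
        g = genes_by_chrom.get(c["chrom"])
        if g is None or len(g) == 0:
            out_rows.append({"ccre_id": c["id"], "gene_id": pd.NA,
                             "distance_bp": np.nan, "ties": "", "unlinked": True})
            continue
        d = _gap(c["start"], c["end"], g["start"].to_numpy(), g["end"].to_numpy())
        dmin = d.min()
        tied = g.loc[d == dmin].sort_values(["start", "end", "id"])
        best = tied.iloc[0]
        ties = ",".join(tied["id"].iloc[1:]) if len(tied) > 1 else ""
        out_rows.append({"ccre_id": c["id"], "gene_id": best["id"],
                         "distance_bp": int(dmin), "ties": ties, "unlinked": False})
    return pd.DataFrame(out_rows)


def tss_distance(ccre, gene) -> tuple[int, bool]:
    """Distance (bp) from a cCRE interval to a gene's strand-aware TSS.

    The TSS is the interval start for + genes and end-1 for - genes
    (0-based).  A cCRE containing the TSS has distance 0.  Distal means
    strictly more than 2000 bp away.
    """
    strand = gene.get("strand", ".") if isinstance(gene, (dict, pd.Series)) else "."
    if strand not in ("+", "-"):
        raise ValueError(f"gene {gene.get('id', '?')} lacks a strand")
    tss = int(gene["start"]) if strand == "+" else int(gene["end"]) - 1
    s, e = int(ccre["start"]), int(ccre["end"])
    if s <= tss < e:
        dist = 0
    else:
        dist = min(abs(s - tss), abs(tss - (e - 1)))
    return dist, dist > 2000


def correlation_sign(gene_traj, ccre_traj) -> tuple[float, str]:
    """Pearson r between fitted trajectories and its regulatory reading:
    enhancer-like when positive, silencer-like when negative.  Constant
    trajectories leave r undefined and raise (such pairs are excluded)."""
    g = np.asarray(gene_traj, dtype=float)
    c = np.asarray(ccre_traj, dtype=float)
    if g.shape != c.shape:
        raise ValueError("trajectories must have equal length")
    if np.ptp(g) == 0 or np.ptp(c) == 0:
        raise ValueError("constant trajectory: correlation undefined")
    r = float(stats.pearsonr(g, c)[0])
    return r, ("enhancer-like" if r > 0 else "silencer-like")


def classify_pattern(gene_id, k_signs, corr_signs, expression_traj) -> GenePatternRecord:
    """Mono/poly pattern and regulatory group of a gene from its linked cCREs.

    Mono-pattern: all linked cCRE k-signs identical (single-cCRE genes are
    mono by definition).  The group's enhancer/silencer side is the majority
    vote of per-pair correlation signs; an exact tie is flagged and the
    group left unset.  ``fold_change`` is max - min of the expression
    trajectory (log2 scale in typical use).
    """
    k_signs = [np.sign(k) for k in k_signs]
    if len(k_signs) == 0:
        raise ValueError("gene has no linked cCREs with acceptable fits")
    pattern = "mono" if len(set(k_signs)) == 1 else "poly"
    pos = sum(1 for s in corr_signs if s > 0)
    neg = sum(1 for s in corr_signs if s < 0)
    traj = np.asarray(expression_traj, dtype=float)
    fc = float(traj.max() - traj.min())
    if pos == neg:
        return GenePatternRecord(gene_id, len(k_signs), pattern, None, fc, sign_tie=True)
    side = "enhancer" if pos > neg else "silencer"
    return GenePatternRecord(gene_id, len(k_signs), pattern, f"{side}-{pattern}", fc)


def build_link_table(ccres: pd.DataFrame, genes: pd.DataFrame,
                     ccre_k: pd.Series, gene_fitted: pd.DataFrame,
                     ccre_fitted: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full linking pass: nearest gene, TSS distance, correlation sign,
    proximity rank, and per-gene pattern records.

    ``ccre_k`` maps cCRE id -> fitted k; ``*_fitted`` are feature x time
    matrices of fitted trajectories.  Pairs with constant trajectories are
    dropped.  Returns (links, gene_patterns).
    """
    genes_by_id = genes.set_index("id")
    links = nearest_gene(ccres, genes)
    links = links[~links["unlinked"]].copy()
    rows = []
    for _, ln in links.iterrows():
        ccre = ccres.loc[ccres["id"] == ln["ccre_id"]].iloc[0]
        gene = genes_by_id.loc[ln["gene_id"]]
        gene = pd.Series(gene)
        gene["id"] = ln["gene_id"]
        tssd, distal = tss_distance(ccre, gene)
        if ln["ccre_id"] not in ccre_fitted.index or ln["gene_id"] not in gene_fitted.index:
            continue
        try:
            r, sign = correlation_sign(gene_fitted.loc[ln["gene_id"]],
                                       ccre_fitted.loc[ln["ccre_id"]])
        except ValueError:
            continue
        rows.append({"ccre_id": ln["ccre_id"], "gene_id": ln["gene_id"],
                     "distance_bp": ln["distance_bp"], "tss_distance": tssd,
                     "is_distal": distal, "r": r, "sign": sign,
                     "k": float(ccre_k.get(ln["ccre_id"], np.nan)),
                     "ties": ln["ties"]})
    links = pd.DataFrame(rows)
    if len(links):
        links["proximity_rank"] = (
            links.sort_values(["gene_id", "distance_bp", "ccre_id"])
            .groupby("gene_id").cumcount() + 1
        )
        links = links.sort_values(["gene_id", "proximity_rank"]).reset_index(drop=True)
    patterns = []
    for gene_id, sub in links.groupby("gene_id"):
        rec = classify_pattern(
            gene_id, sub["k"].to_numpy(),
            np.sign(sub["r"].to_numpy()),
            gene_fitted.loc[gene_id].to_numpy(dtype=float),
        )
        patterns.append(rec.__dict__)
    return links, pd.DataFrame(patterns)


def fit_interaction_model(y, x, z, family: str = "logistic"):
    """Interaction model y ~ a*x + b*z + c*(x:z) (+ intercept).

    ``x`` is the mean linked-cCRE count, ``z`` the binary poly-pattern
    indicator.  ``family`` "logistic" fits by IRLS with a logit link for a
    binary response (term-membership models); "linear" fits OLS for a
    continuous response (fold-change model).  Returns a dict with the a/b/c
    coefficients, their p-values, VIFs of the three predictors, and a
    ``separated`` flag set when the logistic fit is degenerate (perfect
    separation), in which case coefficients are still reported.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    if len(y) <= 10:
        raise ValueError("need more than 10 observations")
    if len(np.unique(z)) < 2:
        raise ValueError("z is constant: interaction is inestimable")
    exog = sm.add_constant(np.column_stack([x, z, x * z]))
    separated = False
    import warnings
    if family == "logistic":
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error", PerfectSeparationWarning)
                res = sm.GLM(y, exog, family=sm.families.Binomial()).fit()
        except (PerfectSeparationError, PerfectSeparationWarning):
            separated = True
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.GLM(y, exog, family=sm.families.Binomial()).fit(maxiter=25)
    elif family == "linear":
        res = sm.OLS(y, exog).fit()
    else:
        raise ValueError("family must be 'logistic' or 'linear'")
    vifs = np.array([variance_inflation_factor(exog, j) for j in range(1, 4)])
    names = ["a", "b", "c"]
    return {
        "coef": dict(zip(names, res.params[1:])),
        "intercept": float(res.params[0]),
        "pvalues": dict(zip(names, res.pvalues[1:])),
        "bse": dict(zip(names, res.bse[1:])),
        "vif": dict(zip(["x", "z", "x:z"], vifs)),
        "separated": separated,
        "result": res,
    }


def hypergeometric_enrichment(hits_in_set, set_size, hits_total, universe):
    """One-sided hypergeometric enrichment p-value for a gene set against a
    user-supplied term membership (no annotation database is bundled)."""
    return float(stats.hypergeom.sf(hits_in_set - 1, universe, hits_total, set_size))
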