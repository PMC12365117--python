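"""Readers and writers for the TSV/BED formats shared by all subcommands.

Matrices are TSV (UTF-8, '.' decimal): first column ``feature_id``, the
remaining headers numeric time points in days.  Raw replicate-level
matrices use headers ``<time>.<replicate>[.<assay>]`` or an accompanying
samples table.  Intervals are 6-column BED.  Column orders of the outputs
are fixed so runs are diffable.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger("chronode")

__all__ = [
    "read_matrix", "write_matrix", "read_bed", "write_bed",
    "read_samples", "parse_sample_headers", "write_params", "PARAMS_COLUMNS",
]

PARAMS_COLUMNS = [
    "feature_id", "converged", "range_used", "k", "b", "a", "mse",
    "direction", "t_switch", "t_minimum", "t_saturation",
    "kinetic_class", "quadrant",
]

BED_COLUMNS = ["chrom", "start", "end", "id", "score", "strand"]


def read_matrix(path) -> pd.DataFrame:
    """Read a feature x timepoint TSV; returns a DataFrame indexed by
    feature_id with float time columns sorted ascending.

    Duplicate feature ids, non-numeric time headers, and ragged rows are
    rejected with the offending id or line number.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        n_cols = len(header)
        for lineno, line in enumerate(fh, start=2):
            if line.strip() and len(line.rstrip("\n").split("\t")) != n_cols:
                raise ValueError(f"{path}: ragged row at line {lineno}")
    try:
        times = [float(h) for h in header[1:]]
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric time header: {exc}") from None
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.columns = times
    dup = df.index[df.index.duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate feature id {dup[0]!r}")
    if np.any(np.diff(times) <= 0):
        logger.info("%s: time columns not in ascending order; reordering", path)
        df = df[sorted(times)]
    return df


def write_matrix(df: pd.DataFrame, path, float_format: str = "%.6g") -> None:
    out = df.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t", float_format=float_format)


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, : len(BED_COLUMNS)]
    df.columns = BED_COLUMNS[: df.shape[1]]
    if "id" not in df.columns:
        df["id"] = [f"iv{i}" for i in range(len(df))]
    if "strand" not in df.columns:
        df["strand"] = "."
    if "score" not in df.columns:
        df["score"] = 0
    bad = df.index[df["start"] >= df["end"]]
    if len(bad):
        raise ValueError(f"{path}: start >= end at record {bad[0] + 1}")
    return df[BED_COLUMNS]


def write_bed(df: pd.DataFrame, path) -> None:
    df[BED_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_samples(path) -> pd.DataFrame:
    """Samples metadata TSV with columns sample, time, replicate[, assay]."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str})
    required = {"sample", "time", "replicate"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: samples table needs columns {sorted(required)}")
    return df


def parse_sample_headers(headers) -> pd.DataFrame:
    """Parse raw-matrix headers '<time>.<replicate>[.<assay>]' into a
    samples table; the time may itself contain a decimal point."""
    rows = []
    for h in headers:
        parts = h.split(".")
        assay = None
        if parts and not parts[-1].lstrip("-").isdigit():
            assay = parts.pop()
        if len(parts) < 2:
            raise ValueError(f"cannot parse sample header {h!r}")
        replicate = parts.pop()
        time = float(".".join(parts))
        rows.append({"sample": h, "time": time, "replicate": replicate,
                     "assay": assay})
    return pd.DataFrame(rows)


def write_params(params: pd.DataFrame, path, float_format: str = "%.6g") -> None:
    """Write a fitted-parameters table with the documented stable column
    order, 6-significant-digit floats, and NA for non-converged fields."""
    out = params.copy()
    for col in PARAMS_COLUMNS:
        if col not in out.columns:
            out[col] = np.nan
    extra = [c for c in out.columns if c not in PARAMS_COLUMNS]
    out = out[PARAMS_COLUMNS + extra]
    out.to_csv(path, sep="\t", index=False, float_format=float_format,
               na_rep="NA")
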