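"""Readers and writers for the pipeline's tabular artifacts.

All files are plain UTF-8 delimited text: comma-separated for ``.csv``,
tab-separated for ``.tsv``. Count matrices are written genes-as-rows with a
``gene_id`` first column, the layout used for published normalized-count
supplements. Missing statistics are written as the literal token ``NA``.
Row and column order is preserved exactly; rejected files produce no output.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .datatypes import (
    CONTRAST_COLUMNS,
    FACTOR_LEVELS,
    CountMatrix,
    DdctTable,
    SampleDesign,
    ValidationError,
)

NA_TOKEN = "NA"

# on-disk column names for contrast tables (R-style capitalisation)
_CONTRAST_DISK = {
    "base_mean": "baseMean",
    "log2fc": "log2FC",
    "lfc_se": "lfcSE",
    "stat": "stat",
    "pvalue": "pvalue",
    "padj": "padj",
}
_CONTRAST_MEM = {v: k for k, v in _CONTRAST_DISK.items()}


def _sep(path) -> str:
    return "\t" if str(path).endswith(".tsv") else ","


def read_count_matrix(path, scale: str = "raw") -> CountMatrix:
    """Read a gene x sample matrix (first column gene ids, header sample ids)."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_sep(path), index_col=0, dtype=str)
    df.index.name = "gene_id"
    numeric = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            gene = df.index[bad.to_numpy().nonzero()[0][0]]
            raise ValidationError(
                f"non-numeric cell at gene {gene!r}, sample {col!r}: {df.loc[gene, col]!r}"
            )
        numeric[col] = vals
    return CountMatrix(numeric, scale=scale)


def write_count_matrix(matrix: CountMatrix, path) -> None:
    data = matrix.data
    if matrix.scale == "raw":
        data = data.astype(np.int64)
    data.to_csv(path, sep=_sep(path), index_label="gene_id")


def read_sample_key(path) -> SampleDesign:
    """Read a sample key (sample_id, age, treatment[, stimulus][, covariates])."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_sep(path))
    if "sample_id" not in df.columns:
        raise ValidationError("sample key is missing column 'sample_id'")
    for col in ("age", "treatment"):
        if col not in df.columns:
            raise ValidationError(f"sample key is missing column {col!r}")
    df = df.set_index("sample_id")
    factor_cols = [c for c in FACTOR_LEVELS if c in df.columns]
    extra = [c for c in df.columns if c not in factor_cols]
    covariates = None
    if extra:
        cov = df[extra].apply(pd.to_numeric, errors="coerce")
        if cov.isna().any().any():
            bad = cov.columns[cov.isna().any()][0]
            raise ValidationError(f"covariate column {bad!r} contains non-numeric values")
        covariates = cov
    return SampleDesign(df[factor_cols], covariates)


def write_sample_key(design: SampleDesign, path) -> None:
    df = design.table.copy()
    if design.covariates is not None:
        df = pd.concat([df, design.covariates], axis=1)
    df.to_csv(path, sep=_sep(path), index_label="sample_id")


def write_results_table(results: pd.DataFrame, path) -> None:
    """Write a contrast result or classification table with deterministic columns.

    Contrast tables get columns ``gene_id, baseMean, log2FC, lfcSE, stat,
    pvalue, padj``; classification tables ``gene_id, direction, category``
    (or ``gene_id, lps_category, prevented_by_repop``) followed by any
    retained statistic columns.
    """
    if len(results) == 0:
        raise ValidationError("refusing to write an empty results table")
    df = results.copy()
    df.index.name = "gene_id"
    if "log2fc" in df.columns and "base_mean" in df.columns:
        out = df[[c for c in CONTRAST_COLUMNS if c != "tested"]].rename(columns=_CONTRAST_DISK)
    elif "category" in df.columns:
        lead = ["direction", "category"]
        out = df[lead + [c for c in df.columns if c not in lead]]
    elif "lps_category" in df.columns:
        lead = ["lps_category", "prevented_by_repop"]
        out = df[lead + [c for c in df.columns if c not in lead]]
    else:
        out = df
    out.to_csv(path, sep=_sep(path), na_rep=NA_TOKEN, index_label="gene_id")


def read_results_table(path) -> pd.DataFrame:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_sep(path), na_values=[NA_TOKEN], keep_default_na=False)
    df = df.set_index("gene_id")
    df = df.rename(columns=_CONTRAST_MEM)
    if "pvalue" in df.columns and "base_mean" in df.columns:
        df["tested"] = df["pvalue"].notna()
    if "prevented_by_repop" in df.columns:
        df["prevented_by_repop"] = df["prevented_by_repop"].astype(bool)
    return df


def write_truth_table(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep=_sep(path), index_label="gene_id")


def read_truth_table(path) -> pd.DataFrame:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    # keep_default_na=False: the planted category "null" is a label, not NaN
    return pd.read_csv(path, sep=_sep(path), index_col="gene_id",
                       na_values=[NA_TOKEN], keep_default_na=False)


def read_ddct_table(path) -> DdctTable:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    return DdctTable(pd.read_csv(path, sep=_sep(path)))


def write_ddct_table(table: DdctTable, path) -> None:
    table.table.to_csv(path, sep=_sep(path), index=False)
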