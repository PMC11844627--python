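"""Readers and writers for the expression-matrix formats the pipeline touches.

Supported inputs: long-format tissue-consensus TSV (one row per gene and
tissue, Human Protein Atlas style), GCT v1.2 count matrices (GTEx style),
and generic delimited gene x sample tables. Sample metadata travels in a
sidecar TSV joined on sample id.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CountMatrix, ExpressionMatrix, MatrixError

__all__ = [
    "read_long_consensus",
    "read_gct",
    "read_matrix",
    "read_counts",
    "read_sample_table",
    "write_matrix",
]


class FormatError(ValueError):
    """Input file does not conform to its declared format."""


def read_long_consensus(
    path: str | Path,
    gene_col: str = "gene",
    sample_col: str = "tissue",
    value_col: str = "value",
    unit: str = "nTPM",
) -> ExpressionMatrix:
    """Pivot a long-format (gene, tissue, value) TSV into a wide matrix.

    Absent (gene, tissue) pairs become NaN — missing, not zero — so that
    genes with patchy coverage can be excluded explicitly downstream.
    Duplicate pairs are an error: the consensus format promises one value
    per gene and tissue.
    """
    df = pd.read_csv(path, sep="\t")
    for col in (gene_col, sample_col, value_col):
        if col not in df.columns:
            raise FormatError(
                f"{path}: missing column {col!r}; found {list(df.columns)}"
            )
    dup = df.duplicated(subset=[gene_col, sample_col])
    if dup.any():
        pairs = df.loc[dup, [gene_col, sample_col]].head(5).to_records(index=False)
        raise FormatError(f"{path}: duplicate (gene, tissue) pairs, e.g. {list(pairs)}")
    wide = df.pivot(index=gene_col, columns=sample_col, values=value_col)
    # preserve first-appearance order rather than pivot's lexicographic sort
    wide = wide.loc[
        df[gene_col].drop_duplicates().tolist(),
        df[sample_col].drop_duplicates().tolist(),
    ]
    wide.index.name = None
    wide.columns.name = None
    return ExpressionMatrix(values=wide, unit=unit, provenance=str(path))


def read_gct(path: str | Path) -> CountMatrix:
    """Read a GCT v1.2 matrix (``#1.2`` header, dims line, Name/Description).

    The declared dimensions must match the body. Files without the ``#1.2``
    sentinel fall back to plain TSV parsing with the first column as gene id.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("#1.2"):
            df = pd.read_csv(path, sep="\t", index_col=0)
            return CountMatrix(values=df)
        dims = fh.readline().split()
        if len(dims) < 2:
            raise FormatError(f"{path}: malformed GCT dims line {dims!r}")
        try:
            n_rows, n_cols = int(dims[0]), int(dims[1])
        except ValueError as exc:
            raise FormatError(f"{path}: malformed GCT dims line {dims!r}") from exc
        df = pd.read_csv(fh, sep="\t")
    if "Description" in df.columns:
        df = df.drop(columns=["Description"])
    df = df.set_index(df.columns[0])
    df.index.name = None
    if df.shape != (n_rows, n_cols):
        raise FormatError(
            f"{path}: header declares {n_rows}x{n_cols} but body is "
            f"{df.shape[0]}x{df.shape[1]}"
        )
    return CountMatrix(values=df)


def read_matrix(
    path: str | Path,
    unit: str,
    allow_missing: bool = False,
) -> ExpressionMatrix:
    """Read a delimited gene x sample matrix (TSV or CSV by extension)."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise MatrixError(f"{path}: duplicated gene ids {dup}")
    if not allow_missing and df.isna().to_numpy().any():
        raise MatrixError(
            f"{path}: matrix contains missing values; pass allow_missing=True "
            "if they are intentional"
        )
    return ExpressionMatrix(values=df, unit=unit, provenance=str(path))


def read_counts(path: str | Path) -> CountMatrix:
    """Read a delimited gene x sample raw count matrix."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    return CountMatrix(values=df)


def read_sample_table(
    path: str | Path,
    sample_col: str = "sample",
) -> pd.DataFrame:
    """Read sidecar sample metadata, indexed by sample id."""
    df = pd.read_csv(path, sep="\t")
    if sample_col not in df.columns:
        raise FormatError(f"{path}: missing sample id column {sample_col!r}")
    df = df.set_index(sample_col)
    if df.index.duplicated().any():
        raise FormatError(f"{path}: duplicated sample ids")
    return df


def write_matrix(
    matrix: ExpressionMatrix | CountMatrix | pd.DataFrame,
    path: str | Path,
) -> None:
    """Write a matrix as TSV/CSV (by extension); read_matrix round-trips it."""
    df = matrix if isinstance(matrix, pd.DataFrame) else matrix.values
    sep = "," if Path(path).suffix.lower() == ".csv" else "\t"
    df.to_csv(path, sep=sep)


def attach_metadata(
    matrix: ExpressionMatrix | CountMatrix,
    samples: pd.DataFrame,
) -> pd.DataFrame:
    """Align a metadata table to a matrix's columns (inner check, no drops)."""
    missing = [s for s in matrix.values.columns if s not in samples.index]
    if missing:
        raise FormatError(f"samples missing from metadata: {missing[:5]}")
    return samples.loc[matrix.values.columns]


def library_size_report(counts: CountMatrix) -> pd.DataFrame:
    """Per-sample library size and its fold ratio to the smallest library."""
    sizes = counts.library_sizes().astype(float)
    return pd.DataFrame(
        {"library_size": sizes, "fold_vs_min": sizes / sizes.min()}
    )
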