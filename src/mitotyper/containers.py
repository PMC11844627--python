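"""In-memory containers shared across the pipeline.

All matrices are pandas DataFrames with genes/pathways as rows and samples as
columns. Thin dataclass wrappers add the unit tag, provenance and the
validation the pipeline relies on (non-negativity, unique identifiers).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "ExpressionMatrix",
    "ScoreMatrix",
    "MitoPPSMatrix",
]


class MatrixError(ValueError):
    """Raised when a matrix violates a structural invariant."""


def _check_ids(df: pd.DataFrame) -> None:
    dup_rows = df.index[df.index.duplicated()].unique().tolist()
    if dup_rows:
        raise MatrixError(f"duplicated row ids: {dup_rows}")
    dup_cols = df.columns[df.columns.duplicated()].unique().tolist()
    if dup_cols:
        raise MatrixError(f"duplicated column ids: {dup_cols}")


@dataclass
class CountMatrix:
    """Raw sequencing read counts, genes x samples, non-negative integers."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        _check_ids(self.values)
        arr = self.values.to_numpy()
        if np.isnan(arr.astype(float)).any():
            raise MatrixError("count matrix contains missing values")
        if (arr < 0).any():
            raise MatrixError("count matrix contains negative entries")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def library_sizes(self) -> pd.Series:
        return self.values.sum(axis=0)


@dataclass
class ExpressionMatrix:
    """Normalized expression, genes x samples, non-negative reals.

    ``unit`` records what the numbers mean ("nTPM", "normalized-count",
    "intensity", ...). Missing values are NaN, never zero: a zero is an
    observed absence of expression, a NaN is a value that was not measured.
    """

    values: pd.DataFrame
    unit: str
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.unit:
            raise MatrixError("expression matrix requires a unit tag")
        _check_ids(self.values)
        # z-scored / log-transformed matrices are legitimately signed
        if not self.unit.startswith(("zscore", "log")):
            arr = self.values.to_numpy(dtype=float)
            if np.nanmin(arr, initial=0.0) < 0:
                bad = self.values.index[(self.values < 0).any(axis=1)].tolist()
                raise MatrixError(f"negative expression values in genes: {bad[:5]}")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())


@dataclass
class ScoreMatrix:
    """Pathway composite scores, pathways x samples.

    A pathway's score in a sample is the arithmetic mean of its member genes'
    expression values present in the input matrix. ``coverage`` is the
    fraction of annotated member genes that were present; pathways below the
    caller's coverage threshold are listed in ``low_coverage`` (scored but
    flagged unreliable) and pathways with no gene present score NaN and are
    listed in ``unscored``.
    """

    values: pd.DataFrame
    unit: str
    coverage: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    low_coverage: list[str] = field(default_factory=list)
    unscored: list[str] = field(default_factory=list)

    @property
    def pathways(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns


@dataclass
class MitoPPSMatrix:
    """Pathway prioritization scores, pathways x samples, positive reals.

    1.0 means average priority relative to the reference sample set; values
    above/below 1 mean the sample prioritizes/deprioritizes the pathway.
    Samples whose scores would create nonfinite ratios are excluded up front
    and listed in ``excluded``.
    """

    values: pd.DataFrame
    reference: list[str]
    excluded: list[str] = field(default_factory=list)

    @property
    def pathways(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns
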