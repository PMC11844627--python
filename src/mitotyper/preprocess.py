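"""Normalization and cleaning: TMM scaling, half-minimum imputation, transforms.

Between-sample normalization matters here because pathway scores are plain
means of expression values: a sample sequenced twice as deeply would score
twice as high on every pathway. The trimmed mean of M-values (TMM) estimates
a per-sample scale factor robust to compositional outliers (a few very highly
expressed genes), so that counts-per-million computed on the effective
library size (library size x factor) are comparable across samples.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .containers import CountMatrix, ExpressionMatrix

__all__ = [
    "NormalizationFactors",
    "ImputationReport",
    "tmm_factors",
    "normalize_counts",
    "filter_and_impute",
    "transform",
]


@dataclass
class NormalizationFactors:
    factors: pd.Series  # per-sample, geometric mean 1
    reference_sample: str
    method: str = "TMM"

    def __post_init__(self) -> None:
        if (self.factors <= 0).any():
            raise ValueError("normalization factors must be positive")


@dataclass
class ImputationReport:
    n_removed_genes: int
    n_imputed_values: int
    fraction_imputed: float
    imputed_value_per_gene: dict[str, float] = field(default_factory=dict)


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    m_trim: float,
    a_trim: float,
    weighted: bool,
) -> float:
    """Log2 TMM factor of one sample against the reference column.

    Genes with a zero count in either column are dropped for the pair; the
    remaining log-ratios (M) are doubly trimmed — the most extreme ``m_trim``
    fraction of M from each tail and ``a_trim`` of average abundance (A) from
    each tail — and averaged with inverse asymptotic-variance weights.
    """
    keep = (obs > 0) & (ref > 0)
    obs, ref = obs[keep].astype(float), ref[keep].astype(float)
    if obs.size == 0:
        return 0.0
    p_obs, p_ref = obs / lib_obs, ref / lib_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    if np.max(np.abs(m)) < 1e-6:
        return 0.0
    n = m.size
    lo_m = np.floor(n * m_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * a_trim) + 1
    hi_a = n + 1 - lo_a
    rm = rankdata(m)
    ra = rankdata(a)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep.any():
        return 0.0
    if weighted:
        # asymptotic variance of M under binomial sampling (delta method)
        v = (lib_obs - obs) / (lib_obs * obs) + (lib_ref - ref) / (lib_ref * ref)
        w = 1.0 / v[keep]
        return float(np.sum(w * m[keep]) / np.sum(w))
    return float(np.mean(m[keep]))


def tmm_factors(
    counts: CountMatrix,
    m_trim: float = 0.30,
    a_trim: float = 0.05,
    weighted: bool = True,
) -> NormalizationFactors:
    """Trimmed-mean-of-M-values scale factors for a raw count matrix.

    The reference column is the sample whose 75th-percentile count fraction
    is closest to the mean 75th percentile (ties broken by column order).
    Factors are re-centered so their geometric mean is 1.
    """
    mat = counts.values.to_numpy(dtype=float)
    lib = mat.sum(axis=0)
    zero = np.flatnonzero(lib == 0)
    if zero.size:
        bad = counts.samples[zero[0]]
        raise ValueError(f"sample {bad!r} has all-zero counts")
    if mat.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")

    q75 = np.array(
        [np.quantile(mat[:, j] / lib[j], 0.75) for j in range(mat.shape[1])]
    )
    ref_idx = int(np.argmin(np.abs(q75 - q75.mean())))

    log_f = np.array(
        [
            _tmm_pair(
                mat[:, j], mat[:, ref_idx], lib[j], lib[ref_idx],
                m_trim, a_trim, weighted,
            )
            for j in range(mat.shape[1])
        ]
    )
    factors = 2.0 ** log_f
    factors /= np.exp(np.mean(np.log(factors)))
    return NormalizationFactors(
        factors=pd.Series(factors, index=counts.samples),
        reference_sample=str(counts.samples[ref_idx]),
    )


def normalize_counts(
    counts: CountMatrix,
    factors: NormalizationFactors,
) -> ExpressionMatrix:
    """Counts per million on the effective library size (lib size x factor)."""
    missing = [s for s in counts.samples if s not in factors.factors.index]
    if missing:
        raise ValueError(f"no normalization factor for samples: {missing[:5]}")
    lib = counts.library_sizes().astype(float)
    eff = lib * factors.factors.loc[counts.samples]
    values = counts.values.astype(float).div(eff, axis=1) * 1e6
    return ExpressionMatrix(
        values=values,
        unit="normalized-count",
        provenance=f"{factors.method} normalized, ref={factors.reference_sample}",
    )


def filter_and_impute(
    intensities: ExpressionMatrix,
    assume_log10: bool = False,
) -> tuple[ExpressionMatrix, ImputationReport]:
    """Drop all-missing genes, then half-minimum impute remaining NaNs.

    Mirrors the standard proteomics treatment of values below the detection
    limit: a protein never seen in any sample carries no information and is
    removed; a protein seen in some samples gets half its smallest observed
    value in the missing cells — a low but nonzero stand-in. When the input
    is log10-transformed intensities, set ``assume_log10`` so imputation
    happens on the linear scale. Idempotent: a second pass changes nothing.
    """
    df = intensities.values.copy()
    all_missing = df.isna().all(axis=1)
    n_removed = int(all_missing.sum())
    df = df.loc[~all_missing]
    if assume_log10:
        df = 10.0 ** df
    gene_min = df.min(axis=1, skipna=True)
    half_min = gene_min / 2.0
    na_mask = df.isna()
    n_imputed = int(na_mask.to_numpy().sum())
    imputed_per_gene = {
        g: float(half_min[g]) for g in df.index[na_mask.any(axis=1)]
    }
    filled = df.where(~na_mask, half_min, axis=0)
    n_cells = filled.size
    report = ImputationReport(
        n_removed_genes=n_removed,
        n_imputed_values=n_imputed,
        fraction_imputed=(n_imputed / n_cells) if n_cells else 0.0,
        imputed_value_per_gene=imputed_per_gene,
    )
    out = ExpressionMatrix(
        values=filled,
        unit="intensity",
        provenance=intensities.provenance + "|half-min imputed",
    )
    return out, report


def transform(
    matrix: ExpressionMatrix,
    mode: str,
    pseudocount: float = 0.0,
) -> ExpressionMatrix:
    """Elementwise/row transforms: ``zscore_by_gene``, ``log10``, ``log2``.

    z-scoring uses the population sd across samples; constant genes map to
    all-zero rows with a warning rather than dividing by zero. Log modes
    require strictly positive entries unless a pseudocount is supplied.
    """
    df = matrix.values
    if mode == "zscore_by_gene":
        mu = df.mean(axis=1)
        sd = df.std(axis=1, ddof=0)
        constant = sd == 0
        if constant.any():
            warnings.warn(
                f"{int(constant.sum())} constant gene(s) z-scored to all zeros",
                stacklevel=2,
            )
        out = df.sub(mu, axis=0).div(sd.where(~constant, 1.0), axis=0)
        out = out.where(~constant, 0.0)
        unit = f"zscore({matrix.unit})"
    elif mode in {"log10", "log2"}:
        shifted = df + pseudocount
        if (shifted <= 0).any().any():
            raise ValueError(
                f"{mode} of nonpositive values; supply a pseudocount"
            )
        out = np.log10(shifted) if mode == "log10" else np.log2(shifted)
        unit = f"{mode}({matrix.unit})"
    else:
        raise ValueError(f"unknown transform mode {mode!r}")
    return ExpressionMatrix(
        values=out, unit=unit, provenance=matrix.provenance + f"|{mode}"
    )
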