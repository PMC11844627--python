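"""Mitochondrial Pathway Prioritization Scores (mitoPPS).

Raw pathway scores confound specialization with mitochondrial content: a
sample with more mitochondria scores higher on every pathway. mitoPPS removes
that bias by working on pathway *ratios* within each sample. For sample Si
and pathway Pi,

    mitoPPS(Si, Pi) = (1 / (n'-1)) * sum over pathways Pn != Pi of
        [ Score(Si,Pi)/Score(Si,Pn) ]
        / [ (1/x') * sum over reference samples Sx of Score(Sx,Pi)/Score(Sx,Pn) ]

with n' pathways and x' reference samples: each within-sample ratio is
normalized by that ratio's average over the reference set, then averaged over
partner pathways. The score is unitless; 1.0 is average priority, above 1 the
sample prioritizes the pathway, below 1 it deprioritizes it. Because every
term is a within-sample ratio, multiplying a sample's expression by any
positive constant (more mitochondria, deeper sequencing) leaves its mitoPPS
untouched, and with the whole dataset as reference the per-pathway mean over
samples is exactly 1.

The reference set is configurable: the whole dataset (atlas-style analyses)
or a designated control group (treatment studies), in which case scores read
as prioritization relative to untreated controls.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import MitoPPSMatrix, ScoreMatrix

__all__ = [
    "compute_mitopps",
    "control_referenced_mitopps",
    "prioritization_percent",
    "log10_mitopps",
    "dynamic_range",
    "finite_check",
    "FiniteCheckReport",
]


@dataclass
class FiniteCheckReport:
    """Samples whose scores would create nonfinite ratios, with the pathways."""

    offending: dict[str, list[str]] = field(default_factory=dict)

    @property
    def samples(self) -> list[str]:
        return list(self.offending)

    def __bool__(self) -> bool:
        return bool(self.offending)


def finite_check(scores: ScoreMatrix | pd.DataFrame) -> FiniteCheckReport:
    """List samples with any zero, negative, NaN or infinite pathway score.

    Any such score would propagate into infinite or undefined ratios, so the
    sample cannot enter a ratio-based analysis as-is.
    """
    df = scores.values if isinstance(scores, ScoreMatrix) else scores
    arr = df.to_numpy(dtype=float)
    bad = ~np.isfinite(arr) | (arr <= 0)
    offending = {}
    for j, sample in enumerate(df.columns):
        if bad[:, j].any():
            offending[str(sample)] = df.index[bad[:, j]].tolist()
    return FiniteCheckReport(offending=offending)


def _pps_from_arrays(
    mat: np.ndarray,
    ref_cols: np.ndarray,
) -> np.ndarray:
    """Vectorized mitoPPS: mat is pathways x samples, strictly positive."""
    n_path, _ = mat.shape
    # ratio[i, j, s] = Score(s, Pi) / Score(s, Pj)
    ratio = mat[:, None, :] / mat[None, :, :]
    denom = ratio[:, :, ref_cols].mean(axis=2)  # mean ratio over reference
    normalized = ratio / denom[:, :, None]
    diag = np.arange(n_path)
    normalized[diag, diag, :] = 0.0  # drop the Pi == Pn term
    return normalized.sum(axis=1) / (n_path - 1)


def compute_mitopps(
    scores: ScoreMatrix | pd.DataFrame,
    reference: list[str] | None = None,
    on_nonfinite: str = "exclude",
) -> MitoPPSMatrix:
    """Pathway prioritization scores for every (pathway, sample).

    ``reference`` defaults to all (retained) samples. Samples flagged by
    :func:`finite_check` are handled per ``on_nonfinite``: ``"exclude"``
    drops them (the default; they are listed in the result), ``"error"``
    raises, and ``"floor"`` lifts nonpositive scores to 1e-3 times the
    smallest positive score before computing.
    """
    df = (scores.values if isinstance(scores, ScoreMatrix) else scores).astype(float)
    if df.shape[0] < 2:
        raise ValueError("mitoPPS needs at least two pathways")

    report = finite_check(df)
    excluded: list[str] = []
    if report:
        if on_nonfinite == "error":
            raise ValueError(f"nonfinite-producing samples: {report.samples}")
        if on_nonfinite == "floor":
            arr = df.to_numpy()
            positive = arr[np.isfinite(arr) & (arr > 0)]
            if positive.size == 0:
                raise ValueError("no positive scores to derive a floor from")
            floor = positive.min() * 1e-3
            df = df.where(np.isfinite(df) & (df > 0), floor)
        elif on_nonfinite == "exclude":
            excluded = report.samples
            df = df.drop(columns=excluded)
        else:
            raise ValueError(f"unknown on_nonfinite policy {on_nonfinite!r}")
    if df.shape[1] == 0:
        raise ValueError("all samples excluded by the finite check")

    if reference is None:
        ref_ids = list(df.columns)
    else:
        ref_ids = [s for s in reference if s in df.columns]
        if not ref_ids:
            raise ValueError("reference sample set is empty (or fully excluded)")
    ref_cols = np.array([df.columns.get_loc(s) for s in ref_ids])

    values = _pps_from_arrays(df.to_numpy(), ref_cols)
    return MitoPPSMatrix(
        values=pd.DataFrame(values, index=df.index, columns=df.columns),
        reference=[str(s) for s in ref_ids],
        excluded=excluded,
    )


def control_referenced_mitopps(
    scores: ScoreMatrix | pd.DataFrame,
    control_ids: list[str],
    on_nonfinite: str = "exclude",
) -> MitoPPSMatrix:
    """mitoPPS against a control reference (untreated / healthy samples).

    Identical formula with the denominator averaged over ``control_ids``
    only; the mean-1 property then holds over the control subset rather than
    all samples. With ``control_ids`` equal to all samples this reduces to
    :func:`compute_mitopps`.
    """
    df = scores.values if isinstance(scores, ScoreMatrix) else scores
    unknown = [s for s in control_ids if s not in df.columns]
    if unknown:
        raise ValueError(f"control ids not in score matrix: {unknown[:5]}")
    return compute_mitopps(scores, reference=control_ids, on_nonfinite=on_nonfinite)


def prioritization_percent(m: MitoPPSMatrix) -> pd.DataFrame:
    """(mitoPPS - 1) x 100: percent extra (or deficit) priority vs average.

    A value of 2.1 reads as +110% prioritization; 0.35 as -65%.
    """
    return (m.values - 1.0) * 100.0


def log10_mitopps(m: MitoPPSMatrix) -> pd.DataFrame:
    """log10 scale (0 = average priority); the usual heatmap scale."""
    return np.log10(m.values)


def dynamic_range(
    m: MitoPPSMatrix,
    sample_subset: list[str] | None = None,
) -> pd.Series:
    """Per-pathway max minus min mitoPPS (linear scale) over a sample set.

    Measures how plastic a pathway's prioritization is across the chosen
    samples — e.g. across an organ atlas versus along one cell line's
    lifespan.
    """
    df = m.values if sample_subset is None else m.values[list(sample_subset)]
    if df.shape[1] == 0:
        raise ValueError("sample subset is empty")
    out = df.max(axis=1) - df.min(axis=1)
    out.name = "dynamic_range"
    return out
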