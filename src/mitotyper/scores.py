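"""Pathway composite scores, gene-list scores, ratios and fold differences.

A pathway score in a sample is the arithmetic mean of the expression of the
pathway's member genes that are present in the matrix — genes, not child
sub-scores, so overlapping children never double-count. Scores inherit the
input's unit, which makes them comparable between samples but not between
pathways (pathways holding multi-copy mtDNA transcripts always rank high);
the prioritization scores in :mod:`mitotyper.mitopps` remove that bias.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotations import PathwayHierarchy
from .containers import ExpressionMatrix, ScoreMatrix

__all__ = [
    "score_pathways",
    "gene_list_score",
    "pathway_ratio",
    "fold_difference",
    "radar_bounds",
]


def score_pathways(
    expr: ExpressionMatrix,
    hierarchy: PathwayHierarchy,
    min_coverage: float = 0.5,
) -> ScoreMatrix:
    """Mean-of-member-genes score for every pathway in the hierarchy.

    Coverage is the fraction of a pathway's annotated genes present in the
    matrix. Pathways under ``min_coverage`` are scored but flagged
    unreliable; pathways with no gene present score NaN and are listed in
    ``unscored`` (never silently zero).
    """
    present = set(expr.genes)
    rows = {}
    coverage = {}
    low, unscored = [], []
    for node in hierarchy.nodes:
        members = sorted(node.genes & present)
        coverage[node.id] = len(members) / len(node.genes) if node.genes else 0.0
        if not members:
            rows[node.id] = pd.Series(np.nan, index=expr.samples)
            unscored.append(node.id)
            continue
        rows[node.id] = expr.values.loc[members].mean(axis=0)
        if coverage[node.id] < min_coverage:
            low.append(node.id)
    values = pd.DataFrame(rows).T.reindex([n.id for n in hierarchy.nodes])
    values.columns = expr.samples
    return ScoreMatrix(
        values=values,
        unit=expr.unit,
        coverage=pd.Series(coverage),
        low_coverage=low,
        unscored=unscored,
    )


@dataclass
class GeneListScore:
    name: str
    scores: pd.Series  # per-sample mean expression of the listed genes
    genes_used: list[str]
    genes_absent: list[str]


def gene_list_score(
    expr: ExpressionMatrix,
    genes: list[str],
    name: str = "custom",
) -> GeneListScore:
    """Per-sample mean expression of an ad-hoc gene list.

    Same semantics as a pathway score; absent genes are reported, and the
    list must hit at least one present gene. Used for bespoke signatures
    such as a fatty-acid-oxidation score or proliferation/senescence indices.
    """
    present = [g for g in genes if g in expr.genes]
    absent = [g for g in genes if g not in expr.genes]
    if not present:
        raise ValueError(f"none of the {len(genes)} listed genes are present")
    return GeneListScore(
        name=name,
        scores=expr.values.loc[present].mean(axis=0),
        genes_used=present,
        genes_absent=absent,
    )


def pathway_ratio(
    scores: ScoreMatrix,
    numerator: str,
    denominator: str,
) -> pd.Series:
    """Per-sample ratio of two pathway scores (e.g. CI:CIII).

    Samples with a zero denominator or missing score yield NaN and are
    reported via the returned series' name metadata rather than silent inf.
    """
    for p in (numerator, denominator):
        if p not in scores.values.index:
            raise KeyError(f"pathway {p!r} not in score matrix")
    num = scores.values.loc[numerator]
    den = scores.values.loc[denominator]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = num / den
    ratio = ratio.where(np.isfinite(ratio), np.nan)
    ratio.name = f"{numerator}:{denominator}"
    return ratio


def fold_difference(
    scores: ScoreMatrix,
    pathway: str,
    group_a: list[str],
    group_b: list[str],
    summary: str = "ratio_of_means",
    paired: bool = False,
) -> dict:
    """Fold difference of one pathway's score between two sample groups.

    ``ratio_of_means`` divides group-mean scores (population-style contrast);
    ``mean_of_ratios`` averages per-pair ratios and suits donor-matched
    designs (``paired=True`` additionally returns the per-pair ratios and
    their range, pairing samples by position).
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    a = scores.values.loc[pathway, group_a].astype(float)
    b = scores.values.loc[pathway, group_b].astype(float)
    if summary == "ratio_of_means":
        return {"fold": float(a.mean() / b.mean()), "summary": summary}
    if summary == "mean_of_ratios":
        if paired:
            if len(group_a) != len(group_b):
                raise ValueError("paired mode needs equally sized groups")
            ratios = a.to_numpy() / b.to_numpy()
        else:
            # all cross pairs
            ratios = (a.to_numpy()[:, None] / b.to_numpy()[None, :]).ravel()
        if not np.all(np.isfinite(ratios)) or np.any(b.to_numpy() <= 0):
            raise ValueError("mean_of_ratios requires positive scores")
        out = {
            "fold": float(np.mean(ratios)),
            "summary": summary,
        }
        if paired:
            out["per_pair"] = ratios.tolist()
            out["range"] = (float(np.min(ratios)), float(np.max(ratios)))
        return out
    raise ValueError(f"unknown summary {summary!r}")


def radar_bounds(values: np.ndarray | pd.DataFrame | pd.Series) -> tuple[float, float]:
    """Radar-chart axis bounds: dataset min minus 10%, max plus 10%.

    Exposed so radar plots of scores or prioritization values are
    reproducible from the same numbers the analysis prints.
    """
    arr = np.asarray(values, dtype=float)
    lo = float(np.nanmin(arr))
    hi = float(np.nanmax(arr))
    return lo - 0.1 * abs(lo), hi + 0.1 * abs(hi)
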