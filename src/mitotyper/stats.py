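"""Multivariate mapping and two-group inference.

PCA, Ward.D2 hierarchical clustering, k-means, Spearman correlation matrices,
and the two-group test decision tree (Shapiro-Wilk and Fligner-Killeen gates
choosing among Student's t, Welch's t, Wilcoxon rank-sum and Brunner-Munzel)
with Hedges' g effect sizes.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import linkage
from sklearn.cluster import KMeans

__all__ = [
    "PCAResult",
    "pca",
    "ward_cluster",
    "kmeans_rows",
    "spearman_matrix",
    "GroupComparison",
    "compare_groups",
    "hedges_g",
]


@dataclass
class PCAResult:
    scores: pd.DataFrame        # samples x components
    loadings: pd.DataFrame      # features x components
    variance_fraction: pd.Series
    centered: bool
    scaled: bool

    def top_loadings(self, component: str, n: int = 10) -> pd.Series:
        """Features contributing most strongly (by |loading|) to one axis."""
        col = self.loadings[component]
        return col.reindex(col.abs().sort_values(ascending=False).index).head(n)


def pca(
    matrix: pd.DataFrame,
    center: bool = True,
    scale: bool = False,
) -> PCAResult:
    """PCA of a feature x sample matrix; samples are the observations.

    SVD-based, like R's prcomp: optional centering (default on) and unit
    scaling (default off) of each feature across samples. The sign of each
    component is fixed by making its largest-|loading| element positive, so
    repeated runs and plots are comparable. Missing values are an error —
    impute first (see preprocessing).
    """
    if matrix.isna().to_numpy().any():
        raise ValueError("matrix has missing values; run imputation first")
    X = matrix.to_numpy(dtype=float).T  # samples x features
    n, p = X.shape
    if n < 2:
        raise ValueError("PCA needs at least two samples")
    if center:
        X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        if (sd == 0).any():
            raise ValueError("cannot scale constant features")
        X = X / sd
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    k = min(n - 1 if center else n, p)
    u, s, vt = u[:, :k], s[:k], vt[:k]
    # sign convention: largest-|loading| entry of each component positive
    flip = np.sign(vt[np.arange(k), np.argmax(np.abs(vt), axis=1)])
    flip[flip == 0] = 1.0
    vt = vt * flip[:, None]
    u = u * flip[None, :]
    comps = [f"PC{i + 1}" for i in range(k)]
    var = s**2
    total = var.sum()
    return PCAResult(
        scores=pd.DataFrame(u * s, index=matrix.columns, columns=comps),
        loadings=pd.DataFrame(vt.T, index=matrix.index, columns=comps),
        variance_fraction=pd.Series(var / total if total > 0 else var, index=comps),
        centered=center,
        scaled=scale,
    )


def ward_cluster(matrix: pd.DataFrame, axis: str = "columns") -> dict:
    """Ward.D2 agglomerative clustering on Euclidean distances.

    ``axis="columns"`` clusters samples, ``"rows"`` clusters features.
    Returns the merge table (scipy linkage format: children, height, size)
    plus the leaf labels. Merge heights are non-decreasing by construction.
    """
    if axis not in {"rows", "columns"}:
        raise ValueError("axis must be 'rows' or 'columns'")
    obs = matrix.to_numpy(dtype=float)
    labels = list(matrix.index)
    if axis == "columns":
        obs = obs.T
        labels = list(matrix.columns)
    if len(labels) < 2:
        raise ValueError("clustering needs at least two items")
    Z = linkage(obs, method="ward")
    return {"linkage": Z, "labels": labels, "heights": Z[:, 2].tolist()}


def kmeans_rows(matrix: pd.DataFrame, k: int, seed: int, n_init: int = 25) -> pd.Series:
    """k-means labels for the rows; seeded and restarted for reproducibility."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k == 1:
        return pd.Series(0, index=matrix.index, name="cluster")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(matrix.to_numpy(dtype=float))
    return pd.Series(labels, index=matrix.index, name="cluster")


def spearman_matrix(
    matrix: pd.DataFrame,
    axis: str = "columns",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs Spearman rank correlations with t-approximation p-values.

    ``axis="columns"`` correlates samples over features (tissue adjacency
    networks); ``"rows"`` correlates features over samples (pathway-pathway
    correlation structure). Ties get average ranks.
    """
    if axis == "columns":
        data = matrix.to_numpy(dtype=float)
        names = list(matrix.columns)
    elif axis == "rows":
        data = matrix.to_numpy(dtype=float).T
        names = list(matrix.index)
    else:
        raise ValueError("axis must be 'rows' or 'columns'")
    if data.shape[0] < 3:
        raise ValueError("need at least 3 paired observations")
    rho, p = sps.spearmanr(data)
    if np.isscalar(rho):  # spearmanr collapses the 2-variable case
        rho = np.array([[1.0, rho], [rho, 1.0]])
        p = np.array([[0.0, p], [p, 0.0]])
    np.fill_diagonal(p, 0.0)
    return (
        pd.DataFrame(rho, index=names, columns=names),
        pd.DataFrame(p, index=names, columns=names),
    )


@dataclass
class GroupComparison:
    test: str                    # student_t | welch_t | wilcoxon | brunner_munzel
    p_value: float
    statistic: float
    normality_p: tuple[float, float]
    variance_p: float
    hedges_g: float
    alpha_gates: float


def compare_groups(
    x: np.ndarray | pd.Series,
    y: np.ndarray | pd.Series,
    alpha_gates: float = 0.05,
) -> GroupComparison:
    """Two-group comparison with gate-test-driven test selection.

    Shapiro-Wilk on each group decides normality (both p > alpha); a
    Fligner-Killeen test decides variance homogeneity. Normal and
    homogeneous: Student's t. Normal, heterogeneous: Welch's t. Non-normal,
    homogeneous: Wilcoxon rank-sum. Non-normal, heterogeneous:
    Brunner-Munzel. All gate p-values are reported alongside the chosen
    test, its p-value, and Hedges' g.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size < 3:
        raise ValueError("each group needs at least 3 observations")
    sw_x = sps.shapiro(x).pvalue
    sw_y = sps.shapiro(y).pvalue
    normal = (sw_x > alpha_gates) and (sw_y > alpha_gates)
    fk_p = sps.fligner(x, y).pvalue
    homogeneous = fk_p > alpha_gates
    if normal and homogeneous:
        test, res = "student_t", sps.ttest_ind(x, y, equal_var=True)
    elif normal:
        test, res = "welch_t", sps.ttest_ind(x, y, equal_var=False)
    elif homogeneous:
        test, res = "wilcoxon", sps.mannwhitneyu(x, y, alternative="two-sided")
    else:
        test, res = "brunner_munzel", sps.brunnermunzel(x, y)
    return GroupComparison(
        test=test,
        p_value=float(res.pvalue),
        statistic=float(res.statistic),
        normality_p=(float(sw_x), float(sw_y)),
        variance_p=float(fk_p),
        hedges_g=hedges_g(x, y),
        alpha_gates=alpha_gates,
    )


def hedges_g(x: np.ndarray | pd.Series, y: np.ndarray | pd.Series) -> float:
    """Cohen's d on the pooled SD with the small-sample correction.

    g = J(df) * (mean(x) - mean(y)) / s_pooled, J(df) = 1 - 3/(4 df - 1),
    df = n_x + n_y - 2.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    if nx < 2 or ny < 2:
        raise ValueError("each group needs at least 2 observations")
    df = nx + ny - 2
    pooled = np.sqrt(((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / df)
    if pooled == 0:
        return 0.0
    d = (x.mean() - y.mean()) / pooled
    correction = 1.0 - 3.0 / (4.0 * df - 1.0)
    return float(d * correction)
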