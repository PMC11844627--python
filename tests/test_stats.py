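import numpy as np
import pandas as pd
import pytest
from scipy.stats import pearsonr, rankdata

from mitotyper import (
    compare_groups,
    hedges_g,
    kmeans_rows,
    pca,
    spearman_matrix,
    ward_cluster,
)


def _matrix(arr) -> pd.DataFrame:
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(
        arr,
        index=[f"F{i}" for i in range(arr.shape[0])],
        columns=[f"S{j}" for j in range(arr.shape[1])],
    )


class TestPCA:
    def test_rank_one_matrix_loads_on_pc1(self):
        v = np.array([1.0, 2.0, 3.0])
        w = np.array([1.0, -1.0, 0.5, 2.0])
        m = _matrix(np.outer(v, w))
        result = pca(m)
        assert result.variance_fraction["PC1"] == pytest.approx(1.0, abs=1e-12)

    def test_variance_fractions_sum_to_one(self, rng):
        m = _matrix(rng.normal(0, 1, (8, 5)))
        result = pca(m)
        assert result.variance_fraction.sum() == pytest.approx(1.0, abs=1e-9)

    def test_loadings_orthonormal(self, rng):
        m = _matrix(rng.normal(0, 1, (8, 5)))
        L = pca(m).loadings.to_numpy()
        assert np.allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-8)

    def test_matches_eigendecomposition_oracle(self, rng):
        """Covariance eigendecomposition is the independent route to PCA."""
        m = _matrix(rng.normal(0, 1, (8, 5)))
        result = pca(m)
        X = m.to_numpy().T
        Xc = X - X.mean(axis=0)
        evals, evecs = np.linalg.eigh(Xc.T @ Xc)
        order = np.argsort(evals)[::-1][: result.loadings.shape[1]]
        for k, col in enumerate(result.loadings.columns):
            expected = evecs[:, order[k]]
            got = result.loadings[col].to_numpy()
            # eigenvectors are sign-ambiguous; compare up to sign
            assert min(
                np.abs(got - expected).max(), np.abs(got + expected).max()
            ) < 1e-9
        var = evals[order] / evals[evals > 1e-12].sum()
        assert np.allclose(
            result.variance_fraction.to_numpy()[: len(order)], var, atol=1e-9
        )

    def test_sign_convention_largest_loading_positive(self, rng):
        m = _matrix(rng.normal(0, 1, (6, 4)))
        L = pca(m).loadings.to_numpy()
        for k in range(L.shape[1]):
            assert L[np.argmax(np.abs(L[:, k])), k] > 0

    def test_zscored_input_equals_correlation_pca(self, rng):
        m = _matrix(rng.lognormal(0, 1, (7, 6)))
        z = (m.T - m.mean(axis=1)) / m.std(axis=1, ddof=1)
        a = pca(z.T, center=True, scale=False)
        b = pca(m, center=True, scale=True)
        assert np.allclose(
            a.variance_fraction.to_numpy(),
            b.variance_fraction.to_numpy(),
            atol=1e-9,
        )

    def test_missing_values_rejected(self):
        m = _matrix([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ValueError, match="missing"):
            pca(m)


def _naive_ward_d2(points: np.ndarray):
    """Hand-coded Lance-Williams Ward.D2 agglomeration (the oracle)."""
    from itertools import combinations

    n = len(points)
    d = {
        (i, j): np.sqrt(((points[i] - points[j]) ** 2).sum())
        for i, j in combinations(range(n), 2)
    }
    sizes = {i: 1 for i in range(n)}
    active = set(range(n))
    heights = []
    next_id = n
    while len(active) > 1:
        (i, j), dij = min(
            ((k, v) for k, v in d.items() if k[0] in active and k[1] in active),
            key=lambda kv: kv[1],
        )
        heights.append(dij)
        ni, nj = sizes[i], sizes[j]
        for k in active - {i, j}:
            nk = sizes[k]
            dik = d[tuple(sorted((i, k)))]
            djk = d[tuple(sorted((j, k)))]
            merged = np.sqrt(
                ((ni + nk) * dik**2 + (nj + nk) * djk**2 - nk * dij**2)
                / (ni + nj + nk)
            )
            d[tuple(sorted((next_id, k)))] = merged
        sizes[next_id] = ni + nj
        active -= {i, j}
        active.add(next_id)
        next_id += 1
    return heights


class TestWardClustering:
    def test_two_clouds_top_split(self):
        rng = np.random.default_rng(0)
        cloud_a = rng.normal(0, 0.1, (4, 3))
        cloud_b = rng.normal(10, 0.1, (4, 3))
        m = pd.DataFrame(
            np.vstack([cloud_a, cloud_b]).T,
            columns=[f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)],
        )
        result = ward_cluster(m, axis="columns")
        from scipy.cluster.hierarchy import fcluster

        labels = fcluster(result["linkage"], t=2, criterion="maxclust")
        assert len(set(labels[:4])) == 1
        assert len(set(labels[4:])) == 1
        assert labels[0] != labels[4]

    def test_six_point_fixture_matches_hand_recursion(self):
        points = np.array(
            [[0.0, 0.0], [0.0, 1.0], [4.0, 0.0], [4.5, 1.0], [10.0, 0.0], [9.0, 2.0]]
        )
        m = pd.DataFrame(points.T, columns=[f"p{i}" for i in range(6)])
        result = ward_cluster(m, axis="columns")
        expected = sorted(_naive_ward_d2(points))
        got = sorted(result["heights"])
        assert np.allclose(got, expected, atol=1e-9)

    def test_heights_non_decreasing(self, rng):
        m = pd.DataFrame(rng.normal(0, 1, (5, 12)))
        heights = ward_cluster(m, axis="columns")["heights"]
        assert all(b >= a - 1e-12 for a, b in zip(heights, heights[1:]))

    def test_axis_rows(self, rng):
        m = pd.DataFrame(rng.normal(0, 1, (6, 4)))
        result = ward_cluster(m, axis="rows")
        assert len(result["labels"]) == 6


class TestKMeans:
    def test_single_cluster(self, rng):
        m = pd.DataFrame(rng.normal(0, 1, (5, 3)))
        labels = kmeans_rows(m, k=1, seed=0)
        assert (labels == 0).all()

    def test_planted_blocks_recovered(self):
        rng = np.random.default_rng(1)
        block_a = rng.normal(0, 0.2, (6, 4))
        block_b = rng.normal(8, 0.2, (6, 4))
        m = pd.DataFrame(np.vstack([block_a, block_b]))
        labels = kmeans_rows(m, k=2, seed=0)
        assert labels.iloc[:6].nunique() == 1
        assert labels.iloc[6:].nunique() == 1
        assert labels.iloc[0] != labels.iloc[6]

    def test_seed_reproducible(self, rng):
        m = pd.DataFrame(rng.normal(0, 1, (20, 5)))
        a = kmeans_rows(m, k=3, seed=7)
        b = kmeans_rows(m, k=3, seed=7)
        assert (a == b).all()


class TestSpearman:
    def test_monotone_and_reversed(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        m = pd.DataFrame({"up": x, "cube": x**3, "down": -x})
        rho, p = spearman_matrix(m, axis="columns")
        assert rho.loc["up", "cube"] == pytest.approx(1.0)
        assert rho.loc["up", "down"] == pytest.approx(-1.0)
        assert np.allclose(np.diag(rho), 1.0)
        assert np.allclose(rho, rho.T)

    def test_ties_match_rank_then_pearson(self):
        a = np.array([1.0, 2.0, 2.0, 3.0, 5.0, 5.0, 5.0, 8.0, 9.0, 9.0])
        b = np.array([2.0, 1.0, 4.0, 4.0, 4.0, 7.0, 6.0, 9.0, 9.0, 12.0])
        m = pd.DataFrame({"a": a, "b": b})
        rho, _ = spearman_matrix(m, axis="columns")
        expected = pearsonr(rankdata(a), rankdata(b)).statistic
        assert rho.loc["a", "b"] == pytest.approx(expected, abs=1e-12)

    def test_too_few_observations(self):
        m = pd.DataFrame({"a": [1.0, 2.0], "b": [2.0, 1.0]})
        with pytest.raises(ValueError, match="at least 3"):
            spearman_matrix(m, axis="columns")


class TestCompareGroups:
    """Each regime is constructed so the gate tests land where intended;
    the chosen test is then fully determined by the decision tree."""

    def test_gaussian_equal_variance_selects_student(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 60)
        y = rng.normal(0.5, 1, 60)
        result = compare_groups(x, y)
        assert result.test == "student_t"
        assert result.normality_p[0] > 0.05 and result.normality_p[1] > 0.05
        assert result.variance_p > 0.05

    def test_gaussian_unequal_variance_selects_welch(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 60)
        y = rng.normal(0.5, 10, 60)
        result = compare_groups(x, y)
        assert result.test == "welch_t"
        assert result.variance_p <= 0.05

    def test_heavy_tailed_equal_spread_selects_wilcoxon(self):
        rng = np.random.default_rng(5)
        x = rng.standard_cauchy(80)
        y = rng.standard_cauchy(80) + 0.3
        result = compare_groups(x, y)
        assert result.test == "wilcoxon"
        assert min(result.normality_p) <= 0.05
        assert result.variance_p > 0.05

    def test_heavy_tailed_unequal_spread_selects_brunner_munzel(self):
        rng = np.random.default_rng(3)
        x = rng.standard_cauchy(80)
        y = rng.standard_cauchy(80) * 12 + 0.3
        result = compare_groups(x, y)
        assert result.test == "brunner_munzel"
        assert min(result.normality_p) <= 0.05
        assert result.variance_p <= 0.05

    def test_symmetric_tests_invariant_to_labeling(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 30)
        y = rng.normal(1, 1, 30)
        ab = compare_groups(x, y)
        ba = compare_groups(y, x)
        assert ab.test == ba.test
        assert ab.p_value == pytest.approx(ba.p_value, abs=1e-12)
        assert ab.hedges_g == pytest.approx(-ba.hedges_g, abs=1e-12)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            compare_groups([1.0, 2.0], [1.0, 2.0, 3.0])


class TestHedgesG:
    def test_identical_groups_zero(self):
        x = np.array([1.0, 2.0, 3.0])
        assert hedges_g(x, x) == 0.0

    def test_sign_flips_on_swap(self, rng):
        x = rng.normal(0, 1, 10)
        y = rng.normal(1, 1, 12)
        assert hedges_g(x, y) == pytest.approx(-hedges_g(y, x), abs=1e-15)

    def test_fixed_vectors_match_hand_formula(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([3.0, 4.0, 5.0, 6.0])
        # pooled sd = sqrt(5/3); d = -2/sqrt(5/3); J = 1 - 3/23
        expected = (-2.0 / np.sqrt(5.0 / 3.0)) * (1.0 - 3.0 / 23.0)
        assert hedges_g(x, y) == pytest.approx(expected, abs=1e-12)
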