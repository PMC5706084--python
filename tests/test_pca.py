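"""Covariance PCA: oracle equivalence, spectra, scree rules, outlier ranking."""

import numpy as np
import pandas as pd
import pytest

import sedsource as ss
from sedsource import pca as P


def brute_force_pca(X):
    """Independent oracle: explicit covariance matrix + symmetric eigensolver."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    centered = X - X.mean(axis=0)
    cov = centered.T @ centered / (n - 1)
    lam, vec = np.linalg.eigh(cov)
    order = np.argsort(lam)[::-1]
    return cov, lam[order], vec[:, order]


class TestCovariancePCA:
    def test_diagonal_covariance(self, matrix_factory):
        # two uncorrelated variables with variances 4 and 1
        rng = np.random.default_rng(0)
        a = np.array([0.0, 2.0, 4.0, 6.0, 8.0]) + 10  # variance 10 -> scale below
        x = np.array([1.0, 3.0, 5.0, 7.0, 9.0])
        x = (x - x.mean()) / x.std(ddof=1) * 2.0 + 5.0  # variance 4
        y = rng.permutation([1.0, 2.0, 3.0, 4.0, 5.0])
        y = (y - y.mean()) / y.std(ddof=1) * 1.0 + 5.0  # variance 1
        # orthogonalise y against x to make them exactly uncorrelated
        xc = x - x.mean()
        yc = y - y.mean()
        yc = yc - (yc @ xc) / (xc @ xc) * xc
        yc = yc / yc.std(ddof=1) + 5.0
        mat = matrix_factory(np.column_stack([x, yc]))
        res = P.covariance_pca(mat)
        assert np.allclose(res.eigenvalues, [4.0, 1.0], atol=1e-10)
        assert np.allclose(res.explained_fraction, [0.8, 0.2], atol=1e-10)

    def test_rank_one_correlated_variables(self, matrix_factory):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        mat = matrix_factory(np.column_stack([x, 2 * x]))
        res = P.covariance_pca(mat)
        assert res.explained_fraction[0] == pytest.approx(1.0)
        assert res.explained_fraction[1] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed, matrix_factory):
        rng = np.random.default_rng(seed)
        n, m = rng.integers(3, 7, size=2)
        X = rng.uniform(0.0, 10.0, size=(n, m))
        res = P.covariance_pca(matrix_factory(X))
        cov, lam, vec = brute_force_pca(X)
        assert np.allclose(res.eigenvalues, lam, atol=1e-10)
        # loadings equal up to sign
        for k in range(len(lam)):
            dot = abs(res.loadings.to_numpy()[:, k] @ vec[:, k])
            if lam[k] > 1e-12:
                assert dot == pytest.approx(1.0, abs=1e-8)
        # trace conservation and normalised fractions
        assert res.eigenvalues.sum() == pytest.approx(np.trace(cov), rel=1e-9)
        assert res.explained_fraction.sum() == pytest.approx(1.0, abs=1e-9)

    def test_reconstruction_with_all_components(self, matrix_factory):
        rng = np.random.default_rng(3)
        X = rng.uniform(0.5, 5.0, size=(8, 4))
        res = P.covariance_pca(matrix_factory(X))
        rebuilt = res.scores.to_numpy() @ res.loadings.to_numpy().T
        assert np.allclose(rebuilt, X - X.mean(axis=0), atol=1e-8)

    def test_orientation_duality_of_nonzero_spectra(self, matrix_factory):
        # nonzero eigenvalues of C = X'X/(n-1) equal those of the Gram matrix
        # XX'/(n-1) for the same centered X
        rng = np.random.default_rng(4)
        X = rng.uniform(0.5, 5.0, size=(6, 4))
        res = P.covariance_pca(matrix_factory(X))
        centered = X - X.mean(axis=0)
        gram = centered @ centered.T / (X.shape[0] - 1)
        lam_gram = np.sort(np.linalg.eigvalsh(gram))[::-1][: len(res.eigenvalues)]
        nz = res.eigenvalues > 1e-10
        assert np.allclose(res.eigenvalues[nz], lam_gram[: nz.sum()], rtol=1e-8)

    def test_constant_matrix_rejected(self, matrix_factory):
        with pytest.raises(ValueError, match="variance"):
            P.covariance_pca(matrix_factory(np.full((4, 3), 2.0)))

    def test_raw_matrix_rejected(self, matrix_factory):
        mat = matrix_factory(np.eye(3) + 1, kind="raw")
        with pytest.raises(ValueError):
            P.covariance_pca(mat)


class TestVarianceWeights:
    def test_single_variable_holds_all_variance(self, matrix_factory):
        X = np.column_stack([[1.0, 5.0, 9.0, 13.0], np.full(4, 2.0)])
        w = P.variable_variance_weights(P.covariance_pca(matrix_factory(X)))
        assert w.iloc[0] == pytest.approx(100.0)
        assert w.iloc[1] == pytest.approx(0.0)

    def test_equal_variance_split(self, matrix_factory):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 4))
        X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1) + 3.0
        w = P.variable_variance_weights(P.covariance_pca(matrix_factory(X)))
        assert np.allclose(w.to_numpy(), 25.0, atol=1e-8)
        assert w.sum() == pytest.approx(100.0)

    def test_wrong_orientation_rejected(self, matrix_factory):
        res = P.covariance_pca(
            matrix_factory(np.random.default_rng(2).uniform(1, 2, (4, 3))),
            orientation=P.SAMPLES_AS_VARIABLES,
        )
        with pytest.raises(ValueError):
            P.variable_variance_weights(res)

    def test_recovers_planted_dominant_share(self, default_run):
        scenario, result, _ = default_run
        w = result.variance_weights
        assert w.idxmax() == scenario.dominant
        # 68 positions estimate the envelope variance with sizeable noise
        assert w[scenario.dominant] == pytest.approx(
            100 * scenario.dominant_share, abs=15.0
        )


class TestEliminateDominant:
    def test_diagonal_arithmetic(self, matrix_factory):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(60, 3))
        X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
        q, _ = np.linalg.qr(X)  # exactly uncorrelated columns
        X = q * np.sqrt([100.0, 10.0, 1.0]) * np.sqrt(59) + 50.0
        mat = matrix_factory(X, chemicals=["dom", "mid", "low"])
        res = P.eliminate_dominant_and_rerun(mat, "dom")
        assert np.allclose(res.explained_fraction, [10 / 11, 1 / 11], atol=1e-8)

    def test_absent_variable(self, matrix_factory):
        mat = matrix_factory(np.random.default_rng(0).uniform(1, 2, (4, 3)))
        with pytest.raises(KeyError):
            P.eliminate_dominant_and_rerun(mat, "nope")

    def test_too_few_remaining(self, matrix_factory):
        mat = matrix_factory(np.random.default_rng(0).uniform(1, 2, (4, 2)))
        with pytest.raises(ValueError):
            P.eliminate_dominant_and_rerun(mat, "chem1")

    def test_reveals_secondary_structure(self, default_run):
        scenario, result, _ = default_run
        assert result.eliminated == scenario.dominant
        red = result.chem_pca_reduced
        assert scenario.dominant not in red.loadings.index
        # after removal no single chemical holds the dominant share any more
        assert red.variable_weights.max() < scenario.dominant_share


class TestScreeSelect:
    @pytest.mark.parametrize(
        "spectrum,expected",
        [
            ([99.0, 0.5, 0.5], 1),
            ([85.0, 13.0, 1.0, 1.0], 2),  # leading pair covers 98% of variance
            ([1.0, 1.0, 1.0, 1.0], 4),  # uniform: ceil(0.95 * 4)
        ],
    )
    def test_cumulative_rule(self, spectrum, expected):
        assert P.scree_select(spectrum) == expected

    def test_largest_drop_rule(self):
        assert P.scree_select([10.0, 9.0, 1.0, 0.9], rule="largest_drop") == 2

    def test_empty_spectrum(self):
        with pytest.raises(ValueError):
            P.scree_select([])


class TestRankScoreOutliers:
    def test_identical_positions_give_no_outliers(self, matrix_factory):
        row = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        mat = matrix_factory(np.tile(row, (6, 1)))  # 6 identical positions
        res = P.covariance_pca(mat, orientation=P.SAMPLES_AS_VARIABLES)
        ranking = P.rank_score_outliers(res, n_components=2)
        assert ranking.selected == []

    def test_displaced_position_ranks_first(self, matrix_factory):
        rng = np.random.default_rng(8)
        X = rng.uniform(1.0, 1.2, size=(10, 20))  # positions x chemicals
        X[3] += np.linspace(0, 3.0, 20)  # one anomalous profile
        mat = matrix_factory(X, points=[f"P{i}" for i in range(10)])
        res = P.covariance_pca(mat, orientation=P.SAMPLES_AS_VARIABLES)
        ranking = P.rank_score_outliers(res, n_components=2)
        assert ranking.ranking[0][0] == "P3"
        assert "P3" in ranking.selected
        assert all(d1 >= d2 for (_, d1), (_, d2) in zip(ranking.ranking, ranking.ranking[1:]))

    def test_planted_sources_all_selected(self, default_run):
        scenario, result, _ = default_run
        planted = {p for s in scenario.sources for p in s.positions}
        assert planted <= set(result.outlier_ranking.selected)

    def test_component_count_validation(self, matrix_factory):
        mat = matrix_factory(np.random.default_rng(1).uniform(1, 2, (4, 6)))
        res = P.covariance_pca(mat, orientation=P.SAMPLES_AS_VARIABLES)
        with pytest.raises(ValueError):
            P.rank_score_outliers(res, n_components=99)

    def test_requires_samples_orientation(self, matrix_factory):
        res = P.covariance_pca(matrix_factory(np.random.default_rng(1).uniform(1, 2, (5, 3))))
        with pytest.raises(ValueError):
            P.rank_score_outliers(res)


class TestSubsetPCA:
    def test_all_classes_equals_full_pca(self, small_registry, matrix_factory):
        rng = np.random.default_rng(9)
        mat = matrix_factory(
            rng.uniform(0.5, 2.0, (6, 3)), chemicals=["metal_a", "pah_b", "hc_c"]
        )
        full = P.covariance_pca(mat, orientation=P.SAMPLES_AS_VARIABLES)
        sub = P.subset_pca(
            mat,
            [ss.ChemClass.HEAVY_METAL, ss.ChemClass.PAH, ss.ChemClass.HYDROCARBON],
            small_registry,
        )
        assert np.allclose(sub.eigenvalues, full.eigenvalues, atol=1e-12)

    def test_empty_selection(self, small_registry, matrix_factory):
        mat = matrix_factory([[1.0, 2.0]], chemicals=["metal_a", "pah_b"])
        with pytest.raises(ValueError):
            P.subset_pca(mat, [ss.ChemClass.AGGREGATE], small_registry)

    def test_constant_subset_degenerate(self, small_registry, matrix_factory):
        vals = np.column_stack([np.ones(5) * 2, np.ones(5), np.arange(5.0) + 1])
        mat = matrix_factory(vals, chemicals=["metal_a", "pah_b", "hc_c"])
        # metals+pah columns are constant: zero covariance in that subset
        with pytest.raises(ValueError, match="variance"):
            P.subset_pca(
                mat,
                [ss.ChemClass.HEAVY_METAL, ss.ChemClass.PAH],
                small_registry,
                orientation=P.CHEMICALS_AS_VARIABLES,
            )
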