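"""Correlation-matrix PCA: standardization, eigenstructure, scores."""

import numpy as np
import pytest

from ynobde import gra
from ynobde.pca import (
    CorrelationPCA,
    correlation_matrix,
    eigendecompose,
    select_components,
    standardize,
)


def power_iteration_eigh(R, n_iter=5000, tol=1e-12):
    """Independent eigendecomposition oracle: power iteration + deflation."""
    R = R.copy().astype(float)
    m = R.shape[0]
    values, vectors = [], []
    rng = np.random.default_rng(0)
    for _ in range(m):
        v = rng.normal(size=m)
        v /= np.linalg.norm(v)
        lam = 0.0
        for _ in range(n_iter):
            w = R @ v
            norm = np.linalg.norm(w)
            if norm < tol:
                break
            w /= norm
            if np.linalg.norm(w - v) < tol or np.linalg.norm(w + v) < tol:
                v = w
                break
            v = w
        lam = float(v @ R @ v)
        values.append(lam)
        vectors.append(v)
        R = R - lam * np.outer(v, v)
    order = np.argsort(values)[::-1]
    return np.array(values)[order], np.stack(vectors, axis=1)[:, order]


class TestStandardize:
    def test_symmetric_column(self):
        Z, means, stds = standardize(np.array([[1.0], [2.0], [3.0]]))
        np.testing.assert_allclose(Z.ravel(), [-1.0, 0.0, 1.0])
        assert means[0] == 2.0 and stds[0] == 1.0

    def test_idempotent(self, rng):
        X = rng.normal(size=(40, 3))
        Z, _, _ = standardize(X)
        Z2, _, _ = standardize(Z)
        np.testing.assert_allclose(Z, Z2, atol=1e-12)

    def test_constant_column_rejected(self):
        X = np.column_stack([np.arange(5.0), np.full(5, 3.0)])
        with pytest.raises(ValueError, match="constant column"):
            standardize(X)


class TestCorrelationMatrix:
    def test_orthogonal_columns_give_identity(self):
        Z, _, _ = standardize(
            np.array([[1.0, 1.0], [1.0, -1.0], [-1.0, 1.0], [-1.0, -1.0]])
        )
        np.testing.assert_allclose(correlation_matrix(Z), np.eye(2), atol=1e-12)

    def test_duplicated_column_gives_unit_correlation(self, rng):
        x = rng.normal(size=30)
        Z, _, _ = standardize(np.column_stack([x, x]))
        R = correlation_matrix(Z)
        assert R[0, 1] == pytest.approx(1.0, abs=1e-12)


class TestEigendecompose:
    def test_identity_matrix(self):
        values, vectors = eigendecompose(np.eye(4))
        np.testing.assert_allclose(values, 1.0)
        np.testing.assert_allclose(
            np.abs(vectors) @ np.abs(vectors.T), np.eye(4), atol=1e-12
        )

    @pytest.mark.parametrize("rho", [-0.6, 0.0, 0.85])
    def test_two_by_two_closed_form(self, rho):
        values, _ = eigendecompose(np.array([[1.0, rho], [rho, 1.0]]))
        np.testing.assert_allclose(values, [1 + abs(rho), 1 - abs(rho)], atol=1e-12)

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            eigendecompose(np.array([[1.0, 0.5], [0.2, 1.0]]))

    def test_matches_power_iteration_oracle(self, rng):
        for _ in range(5):
            Z, _, _ = standardize(rng.normal(size=(60, 5)))
            R = correlation_matrix(Z)
            values, vectors = eigendecompose(R)
            oracle_values, oracle_vectors = power_iteration_eigh(R)
            np.testing.assert_allclose(values, oracle_values, atol=1e-6)
            for j in range(5):
                dot = abs(vectors[:, j] @ oracle_vectors[:, j])
                assert dot == pytest.approx(1.0, abs=1e-5)

    def test_reconstruction(self, rng):
        Z, _, _ = standardize(rng.normal(size=(50, 6)))
        R = correlation_matrix(Z)
        values, vectors = eigendecompose(R)
        np.testing.assert_allclose(
            vectors @ np.diag(values) @ vectors.T, R, atol=1e-8
        )

    def test_sign_convention(self, rng):
        Z, _, _ = standardize(rng.normal(size=(30, 4)))
        _, vectors = eigendecompose(correlation_matrix(Z))
        for j in range(4):
            assert vectors[np.argmax(np.abs(vectors[:, j])), j] > 0


class TestSelectComponents:
    def test_fixed_k(self):
        assert select_components(np.array([3.0, 1.0]), "fixed-k", 2) == 2
        with pytest.raises(ValueError):
            select_components(np.array([3.0, 1.0]), "fixed-k", 5)

    def test_cumulative_threshold(self):
        assert (
            select_components(np.ones(4), "cumulative-threshold", 1.0) == 4
        )
        assert (
            select_components(
                np.array([3.0, 1.0, 0.0, 0.0]), "cumulative-threshold", 0.5
            )
            == 1
        )


class TestTransform:
    def test_zero_row_maps_to_origin(self, rng):
        X = rng.normal(size=(30, 4))
        model = CorrelationPCA.fit(X, n_components=2)
        score = model.transform(model.means[None, :])
        np.testing.assert_allclose(score.scores, 0.0, atol=1e-12)

    def test_score_variances_are_eigenvalues(self, rng):
        X = rng.normal(size=(200, 5)) @ rng.normal(size=(5, 5))
        model = CorrelationPCA.fit(X)
        scores = model.transform(X).scores
        np.testing.assert_allclose(
            scores.var(axis=0, ddof=1), model.eigenvalues, atol=1e-8
        )

    def test_scores_uncorrelated(self, rng):
        X = rng.normal(size=(100, 4)) @ rng.normal(size=(4, 4))
        model = CorrelationPCA.fit(X)
        scores = model.transform(X).scores
        cov = np.cov(scores, rowvar=False)
        off = cov - np.diag(np.diag(cov))
        assert np.abs(off).max() < 1e-8

    def test_column_mismatch_rejected(self, rng):
        model = CorrelationPCA.fit(rng.normal(size=(20, 3)))
        with pytest.raises(ValueError, match="columns"):
            model.transform(np.zeros((2, 4)))


class TestAgainstSklearn:
    """Cross-check against an established PCA implementation."""

    def test_eigenvalues_and_scores(self, rng):
        sklearn_pca = pytest.importorskip("sklearn.decomposition").PCA
        X = rng.normal(size=(80, 5)) @ rng.normal(size=(5, 5))
        Z, _, _ = standardize(X)
        model = CorrelationPCA.fit(X)
        ref = sklearn_pca(n_components=5).fit(Z)
        np.testing.assert_allclose(
            model.eigenvalues, ref.explained_variance_, atol=1e-8
        )
        ours = model.transform(X).scores
        theirs = ref.transform(Z)
        for j in range(5):  # sign conventions differ per component
            assert np.allclose(ours[:, j], theirs[:, j], atol=1e-8) or np.allclose(
                ours[:, j], -theirs[:, j], atol=1e-8
            )


@pytest.fixture(scope="module")
def fitted(fixture_table):
    selected = gra.rank_and_select(fixture_table).selected
    return CorrelationPCA.fit(
        fixture_table.descriptor_matrix(selected),
        n_components=6,
        column_names=selected,
    )


class TestFixtureStatistics:
    """Eigenstructure of the 8 selected descriptors on the Y-NO table."""

    REFERENCE_EIGENVALUES = [
        3.7039, 1.8642, 1.3980, 0.6259, 0.2211, 0.1573, 0.0296, 0.0000,
    ]
    # rows = components, columns = the 8 selected descriptors
    REFERENCE_LOADINGS = [
        [-0.1532, -0.3985, 0.3084, 0.3863, 0.4423, 0.3413, 0.4597, 0.2235],
        [-0.5035, -0.3290, 0.0001, -0.0929, -0.2155, -0.4219, 0.1850, 0.6090],
        [0.0213, -0.2076, -0.6685, -0.5414, 0.1997, 0.3165, 0.2750, 0.0294],
        [0.8325, 0.0471, -0.0684, -0.0798, -0.1917, -0.3043, 0.0950, 0.3940],
        [-0.1589, 0.7964, -0.0431, 0.0081, 0.4025, -0.0457, 0.2491, 0.3352],
        [0.0479, -0.2266, -0.2212, 0.1074, 0.6798, -0.4933, -0.4229, -0.0391],
    ]

    def test_polarizability_electron_count_correlation(self, fitted):
        i = fitted.column_names.index("alpha_pol")
        j = fitted.column_names.index("N_X")
        assert fitted.correlation[i, j] == pytest.approx(0.9331, abs=5e-4)

    def test_eigenvalue_spectrum(self, fitted):
        np.testing.assert_allclose(
            fitted.eigenvalues, self.REFERENCE_EIGENVALUES, atol=5e-3
        )

    def test_rank_deficiency_from_gap_collinearity(self, fitted):
        # dE is E_LUMO - E_HOMO (up to two-decimal rounding of the table),
        # so the correlation matrix is singular to that rounding
        assert fitted.eigenvalues[-1] == pytest.approx(0.0, abs=1e-4)

    def test_cumulative_six_component_contribution(self, fitted):
        assert fitted.cumulative_contribution[5] == pytest.approx(
            0.9963, abs=5e-4
        )

    def test_trace_conservation(self, fitted):
        assert fitted.eigenvalues.sum() == pytest.approx(8.0, abs=1e-8)
        assert fitted.variance_weights.sum() == pytest.approx(1.0, abs=1e-12)

    def test_loadings_match_reference_up_to_sign(self, fitted):
        for j, row in enumerate(self.REFERENCE_LOADINGS):
            np.testing.assert_allclose(
                np.abs(fitted.loadings[:, j]), np.abs(row), atol=5e-3
            )

    def test_fixture_scores_pairwise_uncorrelated(self, fitted, fixture_table):
        scores = fitted.transform(
            fixture_table.descriptor_matrix(fitted.column_names)
        ).scores
        cov = np.cov(scores, rowvar=False)
        off = np.abs(cov - np.diag(np.diag(cov)))
        assert off.max() < 1e-8
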