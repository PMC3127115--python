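"""Correlation-matrix principal component analysis.

Standardize columns to zero mean / unit sample variance (n-1 divisor),
form the correlation matrix R = Z'Z/(n-1), eigendecompose, and project
onto the leading unit eigenvectors.  Variance contributions are
lambda_i / m (the trace of a correlation matrix is m).  Scores are NOT
whitened: they keep variance lambda_i, which matters because they feed a
distance-based regressor downstream.

Eigenvector signs are fixed so each component's largest-magnitude loading
is positive -- one global convention so stored patterns and queries live
in the same frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class ScoreTable:
    """Principal-component scores (n x k) with component names PC1..PCk."""

    scores: np.ndarray
    component_names: tuple[str, ...]


@dataclass
class CorrelationPCA:
    """Fitted correlation-matrix PCA model."""

    column_names: tuple[str, ...]
    means: np.ndarray
    stds: np.ndarray              # sample (n-1) standard deviations
    correlation: np.ndarray       # m x m
    eigenvalues: np.ndarray       # descending, clipped at 0
    loadings: np.ndarray          # column j = unit eigenvector of lambda_j
    n_components: int

    @property
    def variance_weights(self) -> np.ndarray:
        """Variance contributions lambda_i / m; they sum to 1."""
        return self.eigenvalues / len(self.eigenvalues)

    @property
    def cumulative_contribution(self) -> np.ndarray:
        return np.cumsum(self.variance_weights)

    @classmethod
    def fit(
        cls,
        X: np.ndarray,
        n_components: int | None = None,
        column_names: tuple[str, ...] | None = None,
    ) -> "CorrelationPCA":
        X = np.asarray(X, dtype=float)
        Z, means, stds = standardize(X)
        R = correlation_matrix(Z)
        eigenvalues, loadings = eigendecompose(R)
        m = X.shape[1]
        k = m if n_components is None else int(n_components)
        if not 1 <= k <= m:
            raise ValueError(f"n_components must be in 1..{m}, got {k}")
        names = column_names or tuple(f"x{j + 1}" for j in range(m))
        return cls(
            column_names=tuple(names),
            means=means,
            stds=stds,
            correlation=R,
            eigenvalues=eigenvalues,
            loadings=loadings,
            n_components=k,
        )

    def transform(self, X: np.ndarray) -> ScoreTable:
        """Standardize with the fitted means/stds and project onto PC1..PCk."""
        X = np.asarray(X, dtype=float)
        if X.shape[1] != len(self.means):
            raise ValueError(
                f"expected {len(self.means)} columns, got {X.shape[1]}"
            )
        Z = (X - self.means) / self.stds
        k = self.n_components
        return ScoreTable(
            scores=Z @ self.loadings[:, :k],
            component_names=tuple(f"PC{j + 1}" for j in range(k)),
        )


def standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column-wise standardization with the sample (n-1) deviation.

    Returns ``(Z, means, stds)`` with every column of Z at mean 0 and
    sample standard deviation 1.  Constant columns are rejected.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    means = X.mean(axis=0)
    stds = X.std(axis=0, ddof=1)
    degenerate = np.nonzero(stds == 0)[0]
    if degenerate.size:
        raise ValueError(f"constant column(s) at index {degenerate.tolist()}")
    return (X - means) / stds, means, stds


def correlation_matrix(Z: np.ndarray) -> np.ndarray:
    """R = Z'Z/(n-1) for standardized Z; symmetric with unit diagonal."""
    Z = np.asarray(Z, dtype=float)
    n = Z.shape[0]
    if n < 2:
        raise ValueError("need at least 2 rows")
    R = Z.T @ Z / (n - 1)
    return np.clip((R + R.T) / 2.0, -1.0, 1.0)


def eigendecompose(R: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigenpairs of a symmetric correlation matrix, descending.

    Eigenvectors are unit-norm with the largest-magnitude entry positive;
    tiny negative eigenvalues from rank deficiency are clipped to 0.
    """
    R = np.asarray(R, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError("R must be square")
    if np.abs(R - R.T).max() > 1e-8:
        raise ValueError("R must be symmetric")
    eigenvalues, vectors = np.linalg.eigh(R)
    order = np.argsort(eigenvalues)[::-1]
    eigenvalues = eigenvalues[order]
    vectors = vectors[:, order]
    if eigenvalues.min() < -1e-10:
        raise ValueError(
            f"R is not positive semi-definite (lambda_min={eigenvalues.min():.2e})"
        )
    eigenvalues = np.clip(eigenvalues, 0.0, None)
    for j in range(vectors.shape[1]):
        i = np.argmax(np.abs(vectors[:, j]))
        if vectors[i, j] < 0:
            vectors[:, j] = -vectors[:, j]
    return eigenvalues, vectors


def select_components(
    eigenvalues: np.ndarray, policy: str = "fixed-k", value: float = 6
) -> int:
    """Number of components to retain.

    ``fixed-k`` returns ``value``; ``cumulative-threshold`` returns the
    smallest k whose cumulative variance contribution reaches ``value``.
    """
    eigenvalues = np.asarray(eigenvalues, dtype=float)
    m = eigenvalues.size
    if policy == "fixed-k":
        k = int(value)
        if not 1 <= k <= m:
            raise ValueError(f"k must be in 1..{m}, got {k}")
        return k
    if policy == "cumulative-threshold":
        if not 0 < value <= 1:
            raise ValueError(f"threshold must be in (0, 1], got {value}")
        cumulative = np.cumsum(eigenvalues) / m
        # floating error in sum(lambda) ~ m can leave cumulative[-1] < 1
        return int(min(np.searchsorted(cumulative, value - 1e-12) + 1, m))
    raise ValueError(f"unknown policy {policy!r}")
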