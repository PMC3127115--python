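"""Generalized regression neural network (GRNN).

A GRNN is a memory-based kernel regressor: the pattern layer stores the
training inputs verbatim, and a prediction is the Gaussian-kernel-weighted
average of the stored targets,

    Y(x) = sum_i y_i p_i(x) / sum_i p_i(x)

so the only free parameter is the smoothing factor delta.  There is no
iterative training; "fitting" stores (scaled) patterns.

Three kernel conventions are supported, differing only in how delta maps
to the Gaussian width for squared distance d2:

- ``"specht"``  p = exp(-d2 / (2 delta^2))   (the textbook form; default)
- ``"plain"``   p = exp(-d2 / delta^2)
- ``"radbas"``  p = exp(-(0.8326 d / delta)^2)  (delta as half-width at
  half-maximum of the radial basis, the convention of a widespread
  neural-network toolbox)

The conventions are equivalent up to a constant rescaling of delta; they
are exposed because published smoothing factors are only meaningful
together with their convention.  The delta-correction pipeline uses
``plain``, the convention under which its reference results are
reproducible (see the methods note).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

KERNELS = ("specht", "plain", "radbas")
SCALING_MODES = ("none", "zscore", "minmax")

#: Default smoothing-factor grid: 0.02 to 1.00 in steps of 0.02.
DEFAULT_GRID = np.round(np.arange(1, 51) * 0.02, 10)


def _kernel_scale(kernel: str, delta: float) -> float:
    """c such that p = exp(-d2 * c)."""
    if kernel == "specht":
        return 1.0 / (2.0 * delta**2)
    if kernel == "plain":
        return 1.0 / delta**2
    if kernel == "radbas":
        return (0.8326 / delta) ** 2
    raise ValueError(f"unknown kernel {kernel!r}")


@dataclass
class GrnnModel:
    """Stored (scaled) training patterns, targets and smoothing factor."""

    patterns: np.ndarray          # n_train x p, already scaled
    targets: np.ndarray           # length n_train
    delta: float
    kernel: str = "specht"
    center: np.ndarray | None = None  # per-column offset applied to queries
    scale: np.ndarray | None = None   # per-column divisor applied to queries

    def predict(self, Xq: np.ndarray) -> np.ndarray:
        return predict(self, Xq)


def fit(
    X: np.ndarray,
    y: np.ndarray,
    delta: float,
    scale_inputs: str | bool = "none",
    kernel: str = "specht",
) -> GrnnModel:
    """Store the pattern layer.

    scale_inputs
        ``"none"``/False: use raw columns. ``"zscore"``/True: center and
        divide by the sample standard deviation of the patterns.
        ``"minmax"``: map each column's pattern range to [0, 1].
        A constant column gets scale 1 (documented, not an error).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.shape[0]:
        raise ValueError("patterns and targets must have the same length")
    if X.shape[0] < 1:
        raise ValueError("need at least one training pattern")
    if delta <= 0:
        raise ValueError(f"delta must be positive, got {delta}")
    if kernel not in KERNELS:
        raise ValueError(f"unknown kernel {kernel!r}")
    mode = {True: "zscore", False: "none"}.get(scale_inputs, scale_inputs)
    if mode not in SCALING_MODES:
        raise ValueError(f"unknown scaling mode {scale_inputs!r}")
    center = scale = None
    if mode == "zscore":
        center = X.mean(axis=0)
        scale = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.ones(X.shape[1])
        scale = np.where(scale == 0, 1.0, scale)
    elif mode == "minmax":
        center = X.min(axis=0)
        span = X.max(axis=0) - center
        scale = np.where(span == 0, 1.0, span)
    patterns = X if center is None else (X - center) / scale
    return GrnnModel(
        patterns=patterns,
        targets=y,
        delta=float(delta),
        kernel=kernel,
        center=center,
        scale=scale,
    )


def predict(model: GrnnModel, Xq: np.ndarray) -> np.ndarray:
    """Kernel-weighted average of stored targets at each query row.

    If every kernel weight underflows to zero for a query, the target of
    the nearest pattern is returned (squared-distance argmin, ties to the
    lowest pattern index).
    """
    Xq = np.atleast_2d(np.asarray(Xq, dtype=float))
    if Xq.shape[1] != model.patterns.shape[1]:
        raise ValueError(
            f"query has {Xq.shape[1]} columns, patterns have "
            f"{model.patterns.shape[1]}"
        )
    if model.center is not None:
        Xq = (Xq - model.center) / model.scale
    d2 = _sq_distances(Xq, model.patterns)
    weights = np.exp(-d2 * _kernel_scale(model.kernel, model.delta))
    s_d = weights.sum(axis=1)
    out = np.empty(Xq.shape[0])
    ok = s_d > 0
    out[ok] = (weights[ok] * model.targets).sum(axis=1) / s_d[ok]
    if not ok.all():
        out[~ok] = model.targets[np.argmin(d2[~ok], axis=1)]
    return out


def _sq_distances(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Exact pairwise squared Euclidean distances (no dot-product trick)."""
    return ((A[:, None, :] - B[None, :, :]) ** 2).sum(axis=-1)


@dataclass
class DeltaSweepResult:
    """Grid search over the smoothing factor."""

    grid: np.ndarray
    criterion_values: np.ndarray
    best_delta: float
    criterion_name: str


def loo_rmse(
    X: np.ndarray,
    y: np.ndarray,
    delta: float,
    scale_inputs: str | bool = "none",
    kernel: str = "specht",
) -> float:
    """Leave-one-out RMSE over the training set at a given delta.

    Each pattern is removed from the pattern layer before being predicted;
    the scaler is kept from the full pattern set (refitting it per fold
    would change the geometry delta refers to).
    """
    model = fit(X, y, delta, scale_inputs, kernel)
    d2 = _sq_distances(model.patterns, model.patterns)
    weights = np.exp(-d2 * _kernel_scale(kernel, delta))
    np.fill_diagonal(weights, 0.0)
    s_d = weights.sum(axis=1)
    preds = np.empty(len(y))
    ok = s_d > 0
    preds[ok] = (weights[ok] * y).sum(axis=1) / s_d[ok]
    if not ok.all():
        d2_masked = d2.copy()
        np.fill_diagonal(d2_masked, np.inf)
        preds[~ok] = y[np.argmin(d2_masked[~ok], axis=1)]
    return float(np.sqrt(np.mean((y - preds) ** 2)))


def sweep_delta(
    X_train: np.ndarray,
    y_train: np.ndarray,
    criterion: str = "loo-train-rmse",
    grid: np.ndarray = DEFAULT_GRID,
    X_test: np.ndarray | None = None,
    y_test: np.ndarray | None = None,
    scale_inputs: str | bool = "none",
    kernel: str = "specht",
) -> DeltaSweepResult:
    """Evaluate a selection criterion on a delta grid and return the argmin.

    ``loo-train-rmse`` needs no held-out data; ``test-rmse`` scores
    predictions on an explicit held-out set.  Ties go to the smallest
    delta.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0 or (grid <= 0).any():
        raise ValueError("grid must be nonempty with positive deltas")
    if criterion == "loo-train-rmse":
        values = np.array(
            [loo_rmse(X_train, y_train, d, scale_inputs, kernel) for d in grid]
        )
    elif criterion == "test-rmse":
        if X_test is None or y_test is None:
            raise ValueError("test-rmse criterion requires a held-out set")
        values = np.empty(grid.size)
        for i, d in enumerate(grid):
            model = fit(X_train, y_train, d, scale_inputs, kernel)
            values[i] = np.sqrt(np.mean((y_test - predict(model, X_test)) ** 2))
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    best = int(np.argmin(values))  # argmin takes the first (smallest delta) tie
    return DeltaSweepResult(
        grid=grid,
        criterion_values=values,
        best_delta=float(grid[best]),
        criterion_name=criterion,
    )
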