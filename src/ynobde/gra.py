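"""Grey relational analysis (GRA) descriptor ranking.

GRA scores how closely each descriptor series tracks a reference series
(here the experimental homolysis BDE) through Deng's relational
coefficient.  With deviations Delta_i(k) = |x0(k) - xi(k)| computed after a
common normalization, the coefficient is

    r_i(k) = (Dmin + a * Dmax) / (Delta_i(k) + a * Dmax)

where Dmin and Dmax are the double minimum/maximum of the deviations over
all series and positions, and ``a`` is the distinguishing coefficient
(0.5 throughout).  The relation degree of a series is the mean of its
coefficients; descriptors are ranked by degree and selected by a strict
threshold (default 0.8).

Because the descriptor columns carry incommensurate units, every series is
normalized before the deviations are formed.  The default is mean
normalization, x -> x / mean(x), the mode that makes the relation degrees
of the bundled Y-NO table reproducible against their published reference
values; min-max and no-op modes are also available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import DescriptorTable

NORMALIZATION_MODES = ("none", "minmax", "mean")


@dataclass(frozen=True)
class GraConfig:
    """Parameters of the grey relational analysis.

    distinguishing_coefficient
        Deng's ``a`` in (0, 1]; damps the influence of the maximum
        deviation.  0.5 throughout this package.
    normalization
        Per-series preprocessing: ``mean`` (x/mean, default), ``minmax``
        ((x-min)/(max-min)) or ``none``.
    selection_threshold
        Descriptors with relation degree strictly greater than this are
        selected.
    """

    distinguishing_coefficient: float = 0.5
    normalization: str = "mean"
    selection_threshold: float = 0.8

    def __post_init__(self) -> None:
        if not 0 < self.distinguishing_coefficient <= 1:
            raise ValueError(
                "distinguishing coefficient must be in (0, 1], got "
                f"{self.distinguishing_coefficient}"
            )
        if self.normalization not in NORMALIZATION_MODES:
            raise ValueError(f"unknown normalization mode {self.normalization!r}")
        if not 0 < self.selection_threshold < 1:
            raise ValueError(
                f"selection threshold must be in (0, 1), got "
                f"{self.selection_threshold}"
            )


@dataclass
class GraResult:
    """Per-descriptor relational coefficients, degrees, ranking, selection."""

    descriptor_names: tuple[str, ...]
    coefficients: np.ndarray  # m x n, row order = descriptor_names
    degrees: np.ndarray       # length m
    ranking: tuple[str, ...]  # names sorted by degree descending
    selected: tuple[str, ...] # degree > threshold, original column order

    def degree_of(self, name: str) -> float:
        return float(self.degrees[self.descriptor_names.index(name)])


def normalize_series(series: np.ndarray, mode: str = "mean") -> np.ndarray:
    """Normalize one series for GRA comparison.

    ``minmax`` maps to [0, 1] and requires a non-constant series; ``mean``
    divides by the series mean and requires a nonzero mean; ``none`` is the
    identity.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 1 or series.size < 2:
        raise ValueError("series must be 1-D with at least 2 entries")
    if mode == "none":
        return series.copy()
    if mode == "minmax":
        lo, hi = series.min(), series.max()
        if hi == lo:
            raise ValueError("constant series cannot be min-max normalized")
        return (series - lo) / (hi - lo)
    if mode == "mean":
        mu = series.mean()
        if mu == 0:
            raise ValueError("series with zero mean cannot be mean-normalized")
        return series / mu
    raise ValueError(f"unknown normalization mode {mode!r}")


def relational_coefficients(
    reference: np.ndarray,
    contrast: np.ndarray,
    config: GraConfig = GraConfig(),
) -> np.ndarray:
    """Deng relational coefficients of each contrast row against reference.

    Both the reference and every contrast row are normalized with the
    configured mode before the absolute deviations are formed.  If all
    deviations vanish (every series identical to the reference) the
    coefficients are defined as 1.

    Returns an m x n matrix with every entry in (0, 1].
    """
    contrast = np.atleast_2d(np.asarray(contrast, dtype=float))
    ref = normalize_series(np.asarray(reference, dtype=float), config.normalization)
    rows = np.stack(
        [normalize_series(row, config.normalization) for row in contrast]
    )
    if rows.shape[1] != ref.shape[0]:
        raise ValueError("reference and contrast lengths differ")
    delta = np.abs(rows - ref)
    dmin, dmax = delta.min(), delta.max()
    if dmax == 0.0:
        return np.ones_like(delta)
    a = config.distinguishing_coefficient
    return (dmin + a * dmax) / (delta + a * dmax)


def relation_degree(coefficients: np.ndarray) -> np.ndarray:
    """Relation degrees: row means of a coefficient matrix."""
    coefficients = np.atleast_2d(np.asarray(coefficients, dtype=float))
    if coefficients.size == 0:
        raise ValueError("empty coefficient matrix")
    return coefficients.mean(axis=1)


def rank_and_select(
    table: DescriptorTable, config: GraConfig = GraConfig()
) -> GraResult:
    """Rank all descriptors of a table against the experimental BDE.

    Degrees are computed over every molecule in the table (the whole-set
    convention of the reference statistics; see the methods note for the
    leakage caveat).  Ranking is descending by degree with ties broken by
    original column order; selection is strictly greater than the
    threshold.
    """
    if table.n < 2:
        raise ValueError("need at least 2 molecules")
    names = table.descriptor_names
    coefficients = relational_coefficients(
        table.expt, table.descriptor_matrix().T, config
    )
    degrees = relation_degree(coefficients)
    order = sorted(range(len(names)), key=lambda i: (-degrees[i], i))
    ranking = tuple(names[i] for i in order)
    selected = tuple(
        n for n, d in zip(names, degrees) if d > config.selection_threshold
    )
    return GraResult(
        descriptor_names=names,
        coefficients=coefficients,
        degrees=degrees,
        ranking=ranking,
        selected=selected,
    )
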