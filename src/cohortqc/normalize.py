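"""Cross-run intensity normalization.

The unit of data is an *intensity matrix*: a pandas DataFrame of log2
intensities with one row per identifier (precursor, peptide or protein
group) and one column per run; missing values stay missing through every
normalization.

Three algorithms are offered, mirroring the LFQ-style options users expect
from cohort tools:

* ``median`` — shift every column so its median equals the cohort median
  of pre-shift column medians.  The per-run shift is the
  "normalization factor" metric reported at cohort level.
* ``pairwise`` — shifts obtained by least squares on median pairwise
  log-ratios over run pairs with sufficient overlap (the shift-estimation
  core of maxLFQ-style delayed normalization), first run anchored at 0.
* ``quantile`` — classical quantile normalization; complete-case rows
  define the reference distribution (mean of order statistics), columns
  are mapped by rank with ties receiving the mean reference value of their
  tied ranks, and values outside the complete-row range are shifted by the
  edge offset (which keeps the map monotone and idempotent).

Each algorithm is exposed both as a function and as a scikit-learn style
transformer (``fit``/``transform``/``get_params``).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "median_shift_normalize",
    "pairwise_ratio_shift_normalize",
    "quantile_normalize",
    "MedianShiftNormalizer",
    "PairwiseRatioShiftNormalizer",
    "QuantileNormalizer",
    "DisconnectedRunsError",
]


class DisconnectedRunsError(ValueError):
    """The run-overlap graph splits into components; no common scale exists."""


def _check_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    if not isinstance(matrix, pd.DataFrame):
        raise TypeError("intensity matrix must be a pandas DataFrame (rows=ids, cols=runs)")
    if matrix.shape[1] == 0:
        raise ValueError("intensity matrix has no runs")
    return matrix


# ---------------------------------------------------------------------------
# median shift


def median_shift_shifts(matrix: pd.DataFrame) -> pd.Series:
    medians = matrix.median(axis=0, skipna=True)
    target = medians.median()
    return target - medians


def median_shift_normalize(matrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Shift each column so its median equals the cohort median of medians."""
    matrix = _check_matrix(matrix)
    shifts = median_shift_shifts(matrix)
    return matrix.add(shifts, axis=1), shifts


# ---------------------------------------------------------------------------
# pairwise-ratio least squares


def pairwise_ratio_shifts(matrix: pd.DataFrame, min_shared: int = 50) -> pd.Series:
    matrix = _check_matrix(matrix)
    cols = list(matrix.columns)
    n = len(cols)
    if n == 1:
        return pd.Series([0.0], index=cols)
    X = matrix.to_numpy(dtype=float)
    rows_i, rows_j, deltas = [], [], []
    for i in range(n):
        for j in range(i + 1, n):
            both = ~np.isnan(X[:, i]) & ~np.isnan(X[:, j])
            if both.sum() < min_shared:
                continue
            rows_i.append(i)
            rows_j.append(j)
            deltas.append(float(np.median(X[both, i] - X[both, j])))
    if rows_i:
        adj = coo_matrix(
            (np.ones(len(rows_i)), (rows_i, rows_j)), shape=(n, n)
        )
    else:
        adj = coo_matrix((n, n))
    n_comp, labels = connected_components(adj, directed=False)
    if n_comp > 1:
        comps = [
            [c for c, l in zip(cols, labels) if l == k] for k in range(n_comp)
        ]
        raise DisconnectedRunsError(
            f"run-overlap graph is disconnected (min_shared={min_shared}); "
            f"components: {comps}"
        )
    # equations: a_i - a_j = -delta_ij; anchor a_0 = 0
    n_eq = len(deltas) + 1
    A = np.zeros((n_eq, n))
    b = np.zeros(n_eq)
    for k, (i, j, d) in enumerate(zip(rows_i, rows_j, deltas)):
        A[k, i] = 1.0
        A[k, j] = -1.0
        b[k] = -d
    A[-1, 0] = 1.0
    shifts, *_ = np.linalg.lstsq(A, b, rcond=None)
    shifts = shifts - shifts[0]  # exact anchor
    return pd.Series(shifts, index=cols)


def pairwise_ratio_shift_normalize(matrix: pd.DataFrame, min_shared: int = 50
                                   ) -> tuple[pd.DataFrame, pd.Series]:
    """Normalize by least squares on median pairwise log-ratios."""
    shifts = pairwise_ratio_shifts(matrix, min_shared=min_shared)
    return matrix.add(shifts, axis=1), shifts


# ---------------------------------------------------------------------------
# quantile


def _column_quantile_map(col_complete: np.ndarray, reference: np.ndarray):
    """Monotone map from a column's complete-row values onto the reference.

    Tied values receive the mean reference value of their tied ranks; the
    map is extended beyond the knots by a constant shift.
    """
    order = np.argsort(col_complete, kind="stable")
    xs = col_complete[order]
    ys = reference.astype(float)
    knot_x, knot_y = [], []
    start = 0
    while start < len(xs):
        stop = start
        while stop + 1 < len(xs) and xs[stop + 1] == xs[start]:
            stop += 1
        knot_x.append(xs[start])
        knot_y.append(ys[start:stop + 1].mean())
        start = stop + 1
    kx = np.asarray(knot_x)
    ky = np.asarray(knot_y)

    def apply(values: np.ndarray) -> np.ndarray:
        out = np.interp(values, kx, ky)
        below = values < kx[0]
        above = values > kx[-1]
        out[below] = values[below] + (ky[0] - kx[0])
        out[above] = values[above] + (ky[-1] - kx[-1])
        return out

    return apply


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize columns against the complete-row reference."""
    matrix = _check_matrix(matrix)
    complete = matrix.dropna(axis=0)
    if complete.empty:
        raise ValueError("quantile normalization requires at least one complete row")
    sorted_cols = np.sort(complete.to_numpy(dtype=float), axis=0)
    reference = sorted_cols.mean(axis=1)

    out = matrix.copy()
    for col in matrix.columns:
        mapper = _column_quantile_map(complete[col].to_numpy(dtype=float), reference)
        observed = matrix[col].notna()
        out.loc[observed, col] = mapper(matrix.loc[observed, col].to_numpy(dtype=float))
    return out


# ---------------------------------------------------------------------------
# estimator interfaces


class MedianShiftNormalizer(TransformerMixin, BaseEstimator):
    """Median-shift normalization as a transformer.

    Attributes
    ----------
    shifts_ : pandas.Series
        Per-run additive log2 shift estimated by :meth:`fit`.
    """

    def fit(self, X: pd.DataFrame, y=None):
        self.shifts_ = median_shift_shifts(_check_matrix(X))
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return _check_matrix(X).add(self.shifts_, axis=1)


class PairwiseRatioShiftNormalizer(TransformerMixin, BaseEstimator):
    """Pairwise-ratio least-squares normalization as a transformer."""

    def __init__(self, min_shared: int = 50):
        self.min_shared = min_shared

    def fit(self, X: pd.DataFrame, y=None):
        self.shifts_ = pairwise_ratio_shifts(X, min_shared=self.min_shared)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return _check_matrix(X).add(self.shifts_, axis=1)


class QuantileNormalizer(TransformerMixin, BaseEstimator):
    """Quantile normalization as a transformer.

    ``fit`` learns the reference distribution (mean of complete-row order
    statistics) and the per-column rank maps; ``transform`` applies them.
    """

    def fit(self, X: pd.DataFrame, y=None):
        X = _check_matrix(X)
        complete = X.dropna(axis=0)
        if complete.empty:
            raise ValueError("quantile normalization requires at least one complete row")
        sorted_cols = np.sort(complete.to_numpy(dtype=float), axis=0)
        self.reference_ = sorted_cols.mean(axis=1)
        self.column_maps_ = {
            col: _column_quantile_map(complete[col].to_numpy(dtype=float), self.reference_)
            for col in X.columns
        }
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        out = _check_matrix(X).copy()
        for col in X.columns:
            mapper = self.column_maps_[col]
            observed = X[col].notna()
            out.loc[observed, col] = mapper(X.loc[observed, col].to_numpy(dtype=float))
        return out


NORMALIZERS = {
    "median": MedianShiftNormalizer,
    "pairwise": PairwiseRatioShiftNormalizer,
    "quantile": QuantileNormalizer,
}
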