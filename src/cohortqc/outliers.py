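"""Unsupervised outlier detection over the cohort metric matrix.

An isolation forest is built from the original algorithm: each of
``n_trees`` isolation trees is grown on a random subsample of ``psi`` runs
by recursively picking a random metric and a random split value within the
subsample's range until points are isolated or the height limit
``ceil(log2 psi)`` is reached.  Runs that isolate quickly — short average
path length — are anomalous.  The anomaly score of a run with mean path
length ``E(h)`` is::

    s = 2 ** (-E(h) / c(psi))

where ``c(n) = 2 H(n-1) - 2 (n-1)/n`` (with ``H(i) = ln(i) + Euler gamma``,
``c(2) = 1``, ``c(n<=1) = 0``) is the expected path length of an
unsuccessful binary search; a path ending in a leaf of size m is credited
``c(m)`` for the un-built subtree.  Scores lie in (0, 1); values well above
0.5 indicate isolation much faster than average.

Because the 23 cohort metrics carry wildly different units, features are
standardized by median/IQR before fitting (with a MAD, then half-range
fallback when the IQR degenerates); constant metrics are dropped.  Missing
values sit at the feature median (0 after standardization) so they are
neutral to isolation.

The final outlier report combines (by union, by default) the runs whose
anomaly score exceeds ``score_threshold`` with the runs flagged on at
least ``min_flagged_metrics`` of the 23 metrics by the 2-SD rule, each
annotated with its flagged metrics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, OutlierMixin

from .inter import CohortMetricMatrix, flag_low_quality

__all__ = [
    "average_path_length",
    "IsolationForestDetector",
    "AnomalyResult",
    "fit_isolation_forest",
    "score_anomalies",
    "detect_outliers",
    "DEFAULT_SCORE_THRESHOLD",
]

_EULER_GAMMA = 0.5772156649

#: anomaly-score cutoff for reporting a run as an outlier; calibrated on
#: 200 held-out synthetic cohorts (see docs/methods.md) as the point of
#: maximal balanced margin between sensitivity to planted anomalies and
#: the false-positive budget, between the conventions of "score > 0.5
#: means anomalous" and a conservative 0.6
DEFAULT_SCORE_THRESHOLD = 0.53


def average_path_length(n: int) -> float:
    """c(n): expected path length of unsuccessful BST search on n points."""
    if n <= 1:
        return 0.0
    if n == 2:
        return 1.0
    return 2.0 * (math.log(n - 1) + _EULER_GAMMA) - 2.0 * (n - 1) / n


def _build_tree(X: np.ndarray, rng: np.random.Generator, depth: int,
                height_limit: int):
    n = X.shape[0]
    if n <= 1 or depth >= height_limit:
        return ("leaf", n)
    lo = X.min(axis=0)
    hi = X.max(axis=0)
    usable = np.nonzero(hi > lo)[0]
    if usable.size == 0:  # duplicate points
        return ("leaf", n)
    feat = int(rng.choice(usable))
    split = float(rng.uniform(lo[feat], hi[feat]))
    left = X[:, feat] < split
    return (
        "node",
        feat,
        split,
        _build_tree(X[left], rng, depth + 1, height_limit),
        _build_tree(X[~left], rng, depth + 1, height_limit),
    )


def _path_length(tree, x: np.ndarray, depth: int = 0) -> float:
    kind = tree[0]
    if kind == "leaf":
        return depth + average_path_length(tree[1])
    _, feat, split, left, right = tree
    return _path_length(left if x[feat] < split else right, x, depth + 1)


class IsolationForestDetector(OutlierMixin, BaseEstimator):
    """Isolation-forest outlier detector with median/IQR standardization.

    Parameters
    ----------
    n_trees : int
        Number of isolation trees (default 100).
    psi : int or None
        Subsample size per tree; ``None`` means ``min(256, n_samples)``.
    score_threshold : float
        Anomaly-score cutoff used by :meth:`predict`.
    random_state : int or None
        Seed for reproducible forests.

    Attributes
    ----------
    trees_ : list
        The fitted isolation trees.
    psi_, height_limit_ : int
        Effective subsample size and ``ceil(log2 psi)`` depth cap.
    feature_names_, center_, scale_ : standardization state; constant
        features are dropped.
    """

    def __init__(self, n_trees: int = 100, psi: int | None = None,
                 score_threshold: float = DEFAULT_SCORE_THRESHOLD,
                 random_state: int | None = None):
        self.n_trees = n_trees
        self.psi = psi
        self.score_threshold = score_threshold
        self.random_state = random_state

    # -- standardization ---------------------------------------------------
    def _standardize_fit(self, X: pd.DataFrame) -> np.ndarray:
        V = X.to_numpy(dtype=float)
        center = np.nanmedian(V, axis=0)
        q75 = np.nanpercentile(V, 75, axis=0)
        q25 = np.nanpercentile(V, 25, axis=0)
        scale = q75 - q25
        mad = 1.4826 * np.nanmedian(np.abs(V - center), axis=0)
        rng_half = (np.nanmax(V, axis=0) - np.nanmin(V, axis=0)) / 2.0
        scale = np.where(scale > 0, scale, np.where(mad > 0, mad, rng_half))
        keep = np.isfinite(scale) & (scale > 0)
        if not keep.any():
            raise ValueError("all metrics are constant; nothing to isolate")
        self.feature_names_ = [c for c, k in zip(X.columns, keep) if k]
        self.center_ = center[keep]
        self.scale_ = scale[keep]
        return self._standardize_apply(X)

    def _standardize_apply(self, X: pd.DataFrame) -> np.ndarray:
        V = X[self.feature_names_].to_numpy(dtype=float)
        Z = (V - self.center_) / self.scale_
        return np.where(np.isfinite(Z), Z, 0.0)

    # -- estimator API -----------------------------------------------------
    def fit(self, X: pd.DataFrame, y=None):
        """Fit the forest on a runs x metrics frame (or array)."""
        X = pd.DataFrame(X)
        n = X.shape[0]
        if n < 3:
            raise ValueError("isolation forest needs at least 3 runs")
        Z = self._standardize_fit(X)
        self.psi_ = min(self.psi or 256, n)
        self.height_limit_ = int(math.ceil(math.log2(self.psi_)))
        rng = np.random.default_rng(self.random_state)
        self.trees_ = []
        for _ in range(self.n_trees):
            idx = rng.choice(n, size=self.psi_, replace=False)
            self.trees_.append(_build_tree(Z[idx], rng, 0, self.height_limit_))
        self.index_ = list(X.index)
        return self

    def mean_path_lengths(self, X: pd.DataFrame) -> np.ndarray:
        Z = self._standardize_apply(pd.DataFrame(X))
        return np.array([
            float(np.mean([_path_length(t, z) for t in self.trees_])) for z in Z
        ])

    def score_samples(self, X: pd.DataFrame) -> np.ndarray:
        """Anomaly scores in (0, 1); higher means more anomalous."""
        h = self.mean_path_lengths(X)
        return 2.0 ** (-h / average_path_length(self.psi_))

    def decision_function(self, X: pd.DataFrame) -> np.ndarray:
        return self.score_threshold - self.score_samples(X)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """+1 for inliers, -1 for outliers (sklearn convention)."""
        return np.where(self.score_samples(X) > self.score_threshold, -1, 1)


@dataclass
class AnomalyResult:
    run_id: str
    anomaly_score: float
    mean_path_length: float
    is_outlier: bool


def _values_frame(matrix) -> pd.DataFrame:
    if isinstance(matrix, CohortMetricMatrix):
        return matrix.values.T  # runs x metrics
    return pd.DataFrame(matrix)


def fit_isolation_forest(matrix, n_trees: int = 100, psi: int | None = None,
                         score_threshold: float = DEFAULT_SCORE_THRESHOLD,
                         seed: int | None = None) -> IsolationForestDetector:
    """Fit the detector on a CohortMetricMatrix (or runs x metrics frame)."""
    det = IsolationForestDetector(n_trees=n_trees, psi=psi,
                                  score_threshold=score_threshold,
                                  random_state=seed)
    return det.fit(_values_frame(matrix))


def score_anomalies(model: IsolationForestDetector, matrix) -> list[AnomalyResult]:
    X = _values_frame(matrix)
    scores = model.score_samples(X)
    paths = model.mean_path_lengths(X)
    return [
        AnomalyResult(run_id=str(rid), anomaly_score=float(s),
                      mean_path_length=float(h),
                      is_outlier=bool(s > model.score_threshold))
        for rid, s, h in zip(X.index, scores, paths)
    ]


def detect_outliers(anomalies: list[AnomalyResult],
                    matrix: CohortMetricMatrix,
                    policy: str = "union",
                    min_flagged_metrics: int = 7) -> pd.DataFrame:
    """Combine forest outliers with the >=k-metric 2-SD rule.

    Returns a DataFrame (ordered by anomaly score, highest first) with one
    row per reported run: run_id, anomaly_score, n_flagged_metrics and the
    comma-separated flagged metric list explaining which metrics deviate.
    """
    if policy not in ("union", "intersection"):
        raise ValueError("policy must be 'union' or 'intersection'")
    forest = {a.run_id for a in anomalies if a.is_outlier}
    sd_rule = flag_low_quality(matrix, min_flagged_metrics=min_flagged_metrics)
    chosen = forest | sd_rule if policy == "union" else forest & sd_rule
    by_run = {a.run_id: a for a in anomalies}
    nflag = matrix.n_flagged()
    rows = [
        {
            "run_id": rid,
            "anomaly_score": by_run[rid].anomaly_score if rid in by_run else float("nan"),
            "n_flagged_metrics": int(nflag.get(rid, 0)),
            "flagged_metrics": ",".join(matrix.flagged_metrics(rid)),
        }
        for rid in chosen
    ]
    report = pd.DataFrame(rows, columns=["run_id", "anomaly_score",
                                         "n_flagged_metrics", "flagged_metrics"])
    return report.sort_values("anomaly_score", ascending=False).reset_index(drop=True)
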