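"""Cohort-level (inter-experiment) metrics, scoring and flagging.

Twenty-three metrics summarise each run against the rest of its cohort:

* **SP1–SP3** — contaminant-panel intensity fractions (erythrocyte,
  cellular debris, serum high-abundance by default): summed intensity of
  protein groups containing a panel member over total protein intensity.
* **LC1–LC2** — retention-time stability: the per-run median \\|deltaRT\\|
  and the per-run mean of the pairwise RT mean-squared-error matrix,
  where ``MSE(i, j)`` is the mean squared RT difference over precursors
  identified in both runs.
* **MS1–MS18** — six distribution statistics (identification count,
  median log2 intensity, IQR, robust SD = 1.4826 x MAD, median pairwise
  Pearson correlation, median-normalization factor) at each of the
  precursor, peptide and protein-group levels.

Scoring exploits the assumption that most of the proteome does not change
across a controlled cohort, so the per-metric median is the reference:
values on the good side of the median score 5, degrading linearly to 1 at
two standard deviations in the bad direction, where the run is flagged.
A run flagged on at least ``min_flagged_metrics`` metrics (default 7) is
reported as low quality.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .normalize import median_shift_shifts
from .registry import inter_registry, load_panels_config
from .report_io import IdentReport, ScanTable

__all__ = [
    "ContaminantPanel",
    "InterConfig",
    "CohortMetricMatrix",
    "load_panels",
    "contaminant_fraction",
    "rt_deviation_metrics",
    "intensity_matrix",
    "quant_distribution_metrics",
    "robust_sd",
    "build_cohort_matrix",
    "flag_low_quality",
]


@dataclass(frozen=True)
class ContaminantPanel:
    """A named set of contaminant protein accessions / gene symbols."""

    panel_id: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"panel {self.panel_id} is empty")
        object.__setattr__(self, "members", frozenset(m.upper() for m in self.members))


def load_panels(path=None) -> dict[str, ContaminantPanel]:
    cfg = load_panels_config(path)
    return {pid: ContaminantPanel(pid, frozenset(members)) for pid, members in cfg.items()}


@dataclass
class InterConfig:
    """Knobs of the cohort analysis (documented defaults)."""

    min_shared: int = 50          # precursor overlap required per run pair
    sd_multiplier: float = 2.0    # flag beyond this many SDs in the bad direction
    min_runs_for_scoring: int = 3
    min_flagged_metrics: int = 7  # low-quality rule: >= this many flagged metrics


@dataclass
class CohortMetricMatrix:
    """Values, scores and flags of the cohort metrics across runs.

    ``values``/``scores``/``flags`` are metric x run DataFrames;
    ``pairwise`` holds named square run x run matrices (``rt_mse``,
    ``pearson_log2_protein``).  ``scored`` is False when the cohort was too
    small for scores and flags (values are still reported).
    """

    runs: list[str]
    values: pd.DataFrame
    scores: pd.DataFrame
    flags: pd.DataFrame
    pairwise: dict[str, pd.DataFrame] = field(default_factory=dict)
    scored: bool = True

    def flagged_metrics(self, run_id: str) -> list[str]:
        col = self.flags[run_id]
        return [m for m in col.index if bool(col.loc[m])]

    def n_flagged(self) -> pd.Series:
        return self.flags.sum(axis=0).astype(int)


# ---------------------------------------------------------------------------
# SP metrics


def contaminant_fraction(report: IdentReport, panel: ContaminantPanel) -> float:
    """Summed panel protein intensity over total protein intensity."""
    prot = report.records.groupby("protein_group")["protein_intensity"].first().dropna()
    total = float(prot.sum())
    if total <= 0:
        return float("nan")
    hits = [
        g for g in prot.index
        if any(acc.strip().upper() in panel.members for acc in str(g).split(";"))
    ]
    return float(prot.loc[hits].sum() / total)


# ---------------------------------------------------------------------------
# LC metrics


def rt_deviation_metrics(reports: list[IdentReport], min_shared: int = 50
                         ) -> tuple[pd.Series, pd.DataFrame]:
    """Per-run median |deltaRT| and the pairwise RT MSE matrix.

    ``MSE(i, j)`` is the mean of squared apex-RT differences over precursor
    ids identified in both runs; pairs sharing fewer than ``min_shared``
    precursors are left non-computable (NaN).
    """
    if len(reports) < 2:
        raise ValueError("RT deviation metrics require at least 2 runs")
    runs = [r.run_id for r in reports]
    lc1 = pd.Series(
        [float(r.records["delta_rt"].abs().median()) for r in reports], index=runs
    )
    rt = pd.DataFrame(
        {r.run_id: r.records.set_index("precursor_id")["apex_rt"] for r in reports}
    )
    X = rt.to_numpy(dtype=float)
    n = len(runs)
    mse = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        both = ~np.isnan(X[:, i]) & ~np.isnan(X[:, j])
        if both.sum() < min_shared:
            mse[i, j] = mse[j, i] = np.nan
        else:
            d = X[both, i] - X[both, j]
            mse[i, j] = mse[j, i] = float(np.mean(d * d))
    return lc1, pd.DataFrame(mse, index=runs, columns=runs)


# ---------------------------------------------------------------------------
# MS metrics


def robust_sd(values) -> float:
    """Robust standard deviation: 1.4826 x median absolute deviation."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        return float("nan")
    return float(1.4826 * np.median(np.abs(x - np.median(x))))


def intensity_matrix(reports: list[IdentReport], level: str) -> pd.DataFrame:
    """log2 intensity matrix (rows = identifiers, columns = runs)."""
    cols = {}
    for r in reports:
        rec = r.records
        if level == "precursor":
            s = rec.set_index("precursor_id")["precursor_intensity"]
        elif level == "peptide":
            if rec["peptide_intensity"].notna().any():
                s = rec.groupby("stripped_sequence")["peptide_intensity"].first()
            else:
                s = rec.groupby("stripped_sequence")["precursor_intensity"].sum(min_count=1)
        elif level == "protein":
            s = rec.groupby("protein_group")["protein_intensity"].first()
        else:
            raise ValueError(f"unknown level {level!r}")
        s = s[s > 0]
        cols[r.run_id] = np.log2(s)
    return pd.DataFrame(cols)


_STATS = ["count", "median_log2", "iqr_log2", "robust_sd_log2",
          "median_pearson", "norm_factor_log2"]


def quant_distribution_metrics(reports: list[IdentReport], level: str,
                               min_shared: int = 50) -> pd.DataFrame:
    """The six distribution statistics per run at one quantification level.

    Returns a run x statistic DataFrame with columns ``count``,
    ``median_log2``, ``iqr_log2``, ``robust_sd_log2``, ``median_pearson``
    and ``norm_factor_log2``.
    """
    mat = intensity_matrix(reports, level)
    runs = [r.run_id for r in reports]
    out = pd.DataFrame(index=runs, columns=_STATS, dtype=float)
    out["count"] = mat.notna().sum(axis=0).astype(float)
    out["median_log2"] = mat.median(axis=0)
    q75 = mat.quantile(0.75, axis=0)
    q25 = mat.quantile(0.25, axis=0)
    out["iqr_log2"] = q75 - q25
    out["robust_sd_log2"] = [robust_sd(mat[c].dropna()) for c in runs]
    if len(runs) >= 2:
        corr = mat.corr(method="pearson", min_periods=min_shared)
        np.fill_diagonal(corr.values, np.nan)
        out["median_pearson"] = corr.median(axis=0)
    else:
        out["median_pearson"] = np.nan
    out["norm_factor_log2"] = median_shift_shifts(mat)
    return out


# ---------------------------------------------------------------------------
# cohort matrix


def _score_row(values: np.ndarray, direction: str, sd_multiplier: float
               ) -> tuple[np.ndarray, np.ndarray]:
    """Score one metric across runs: 5 on the good side of the median,
    linear to 1 at ``sd_multiplier`` SDs in the bad direction; flag beyond."""
    v = values.astype(float)
    if direction == "bad_abs":
        v = np.abs(v)
        direction = "bad_high"
    finite = np.isfinite(v)
    scores = np.full(v.shape, np.nan)
    flags = np.zeros(v.shape, dtype=bool)
    if finite.sum() < 2:
        scores[finite] = 5.0
        return scores, flags
    med = float(np.median(v[finite]))
    sd = float(np.std(v[finite], ddof=1))
    dev = (v - med) if direction == "bad_high" else (med - v)
    if sd == 0 or not np.isfinite(sd):
        scores[finite] = 5.0
        return scores, flags
    lim = sd_multiplier * sd
    with np.errstate(invalid="ignore"):
        raw = 5.0 - 4.0 * np.clip(dev, 0.0, None) / lim
    scores[finite] = np.clip(raw[finite], 1.0, 5.0)
    flags[finite] = dev[finite] > lim
    return scores, flags


def build_cohort_matrix(reports: list[IdentReport],
                        scan_tables: list[ScanTable] | None = None,
                        panels: dict[str, ContaminantPanel] | None = None,
                        config: InterConfig | None = None) -> CohortMetricMatrix:
    """Assemble the 23 x n cohort metric matrix with scores and 2-SD flags.

    Cohorts with fewer than ``config.min_runs_for_scoring`` runs report
    values only (``scored=False``).  ``scan_tables`` is accepted for
    interface symmetry; the cohort metrics derive from the identification
    reports.
    """
    cfg = config or InterConfig()
    panels = panels or load_panels()
    reg = inter_registry()
    runs = [r.run_id for r in reports]
    if len(set(runs)) != len(runs):
        raise ValueError("duplicate run_ids in cohort")
    if len(reports) < 2:
        raise ValueError("a cohort needs at least 2 runs")

    values = pd.DataFrame(index=list(reg.index), columns=runs, dtype=float)

    sp_ids = [m for m in reg.index if str(m).startswith("SP")]
    for sp_id, (panel_id, panel) in zip(sp_ids, panels.items()):
        values.loc[sp_id] = [contaminant_fraction(r, panel) for r in reports]

    lc1, mse = rt_deviation_metrics(reports, min_shared=cfg.min_shared)
    values.loc["LC1"] = lc1
    masked = mse.copy()
    np.fill_diagonal(masked.values, np.nan)
    values.loc["LC2"] = masked.mean(axis=1, skipna=True)

    pairwise = {"rt_mse": mse}
    for level in ("precursor", "peptide", "protein"):
        stats = quant_distribution_metrics(reports, level, min_shared=cfg.min_shared)
        for stat in _STATS:
            mid = reg.index[(reg["level"] == level) & (reg["statistic"] == stat)]
            values.loc[mid[0]] = stats[stat]
    prot_mat = intensity_matrix(reports, "protein")
    pearson = prot_mat.corr(method="pearson", min_periods=cfg.min_shared)
    np.fill_diagonal(pearson.values, 1.0)
    pairwise["pearson_log2_protein"] = pearson

    scores = pd.DataFrame(np.nan, index=values.index, columns=runs)
    flags = pd.DataFrame(False, index=values.index, columns=runs)
    scored = len(reports) >= cfg.min_runs_for_scoring
    if scored:
        for mid in values.index:
            s, f = _score_row(values.loc[mid].to_numpy(dtype=float),
                              str(reg.loc[mid, "direction"]), cfg.sd_multiplier)
            scores.loc[mid] = s
            flags.loc[mid] = f
    return CohortMetricMatrix(runs=runs, values=values, scores=scores,
                              flags=flags, pairwise=pairwise, scored=scored)


def flag_low_quality(matrix: CohortMetricMatrix,
                     min_flagged_metrics: int = 7) -> set[str]:
    """Runs flagged on at least ``min_flagged_metrics`` metrics."""
    counts = matrix.n_flagged()
    return set(counts.index[counts >= min_flagged_metrics])
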