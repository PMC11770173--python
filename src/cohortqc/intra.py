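"""Per-run (intra-experiment) quality metrics and score decompositions.

The heart of the module is the multiplicative decomposition of the
identification outcome of a run.  For DDA::

    N_identified_precursors = N_acquired_MS2 * Q_MS2 * P_MS2_per_precursor

and for DIA, where one multiplexed MS2 scan can identify several precursors
and one precursor is typically identified in several consecutive scans::

    N_identified_precursors = N_acquired_MS2 * Q_MS2 * (complexity / dup_rate)

with

* ``Q_MS2`` — fraction of acquired MS2 scans yielding at least one
  identification;
* ``complexity`` (spectra complexity) — redundant identified precursors per
  identified MS2 scan;
* ``dup_rate`` — redundant identified precursors per unique precursor
  (>= 1);
* ``complexity / dup_rate`` — the utilization rate of MS2 scans, i.e.
  unique precursors per identified MS2 scan.

All four factors derive from one precursor-to-scan assignment table, so the
identity holds exactly by construction.  Identification reports carry, per
precursor, only the *number* of identified MS2 scans (``n_ms2_matched``);
the scan-level assignment is reconstructed geometrically: a precursor may
match any MS2 scan whose isolation window contains its measured m/z and
whose RT lies within half a peak width of the apex, and the
``n_ms2_matched`` nearest-in-RT candidates are taken.

The remaining functions compute the per-run metric catalogue (see
``registry.intra_registry``) across the six workflow categories: sample,
chromatography, DIA windows, ion source, MS1/MS2 signal, identification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .registry import intra_registry
from .report_io import IdentReport, ScanTable

__all__ = [
    "MetricValue",
    "DiaScoreDecomposition",
    "DdaScoreDecomposition",
    "Ms1Feature",
    "decompose_dia_score",
    "decompose_dda_score",
    "compute_scan_metrics",
    "compute_ident_metrics",
    "compute_chromatography_metrics",
    "compute_window_metrics",
    "detect_ms1_features",
    "rt_histogram",
    "per_window_precursor_counts",
]


@dataclass
class MetricValue:
    """One computed metric for one run.

    ``computable=False`` values carry a ``reason`` and no number; scoring
    excludes them from averages instead of treating them as zero.
    """

    metric_id: str
    run_id: str
    value: float | None
    unit: str = ""
    category: str = ""
    computable: bool = True
    reason: str | None = None
    score: float | None = None
    flag: bool | None = None


def _mv(metric_id: str, run_id: str, value) -> MetricValue:
    reg = intra_registry()
    unit = str(reg.loc[metric_id, "unit"]) if metric_id in reg.index else ""
    cat = str(reg.loc[metric_id, "category"]) if metric_id in reg.index else ""
    if value is None or (isinstance(value, float) and not math.isfinite(value)):
        return MetricValue(metric_id, run_id, None, unit, cat, computable=False,
                           reason="not computable from inputs")
    return MetricValue(metric_id, run_id, float(value), unit, cat)


def _not_computable(metric_id: str, run_id: str, reason: str) -> MetricValue:
    reg = intra_registry()
    unit = str(reg.loc[metric_id, "unit"]) if metric_id in reg.index else ""
    cat = str(reg.loc[metric_id, "category"]) if metric_id in reg.index else ""
    return MetricValue(metric_id, run_id, None, unit, cat, computable=False, reason=reason)


# ---------------------------------------------------------------------------
# score decompositions


@dataclass
class DiaScoreDecomposition:
    """The five factors of the DIA identification decomposition.

    Derived quantities are computed from the four underlying counts in
    ``from_counts`` so the algebraic identity
    ``n_unique_precursors == n_acquired_ms2 * q_ms2 * utilization`` is
    exact up to floating-point rounding.
    """

    n_acquired_ms2: int
    n_identified_ms2: int
    n_redundant_precursors: int
    n_unique_precursors: int
    q_ms2: float = field(init=False)
    spectra_complexity: float = field(init=False)
    dup_rate: float = field(init=False)
    utilization: float = field(init=False)

    def __post_init__(self) -> None:
        if self.n_acquired_ms2 <= 0:
            raise ValueError("a DIA run must contain acquired MS2 scans")
        self.q_ms2 = self.n_identified_ms2 / self.n_acquired_ms2
        if self.n_identified_ms2 > 0:
            self.spectra_complexity = self.n_redundant_precursors / self.n_identified_ms2
        else:
            self.spectra_complexity = float("nan")
        if self.n_unique_precursors > 0:
            self.dup_rate = self.n_redundant_precursors / self.n_unique_precursors
        else:
            self.dup_rate = float("nan")
        self.utilization = self.spectra_complexity / self.dup_rate

    @classmethod
    def from_counts(cls, n_acquired_ms2: int, n_identified_ms2: int,
                    n_redundant_precursors: int, n_unique_precursors: int
                    ) -> "DiaScoreDecomposition":
        return cls(int(n_acquired_ms2), int(n_identified_ms2),
                   int(n_redundant_precursors), int(n_unique_precursors))

    def first_level_values(self) -> dict[str, float]:
        return {
            "identified_precursors": float(self.n_unique_precursors),
            "acquired_ms2": float(self.n_acquired_ms2),
            "q_ms2": self.q_ms2,
            "spectra_complexity": self.spectra_complexity,
            "dup_rate": self.dup_rate,
        }


@dataclass
class DdaScoreDecomposition:
    """DDA decomposition: one precursor per identified MS2 scan."""

    n_acquired_ms2: int
    n_identified_ms2: int
    n_unique_precursors: int
    q_ms2: float = field(init=False)
    p_ms2_per_precursor: float = field(init=False)
    computable: bool = field(init=False)

    def __post_init__(self) -> None:
        if self.n_acquired_ms2 <= 0:
            raise ValueError("a DDA run must contain acquired MS2 scans")
        self.q_ms2 = self.n_identified_ms2 / self.n_acquired_ms2
        if self.n_identified_ms2 > 0:
            self.p_ms2_per_precursor = self.n_unique_precursors / self.n_identified_ms2
            self.computable = True
        else:
            self.p_ms2_per_precursor = float("nan")
            self.computable = False


def _reconstruct_assignment(report: IdentReport, scans: ScanTable
                            ) -> tuple[np.ndarray, int]:
    """Reconstruct the precursor -> MS2-scan assignment table.

    Returns (per-record matched-scan counts, number of distinct identified
    MS2 scans).  Candidates for a precursor are the MS2 scans whose
    isolation window contains its measured m/z and whose RT is within half
    a peak width of the apex; the ``n_ms2_matched`` nearest in RT are kept
    (all candidates when ``n_ms2_matched`` is absent).
    """
    rec = report.records
    ms2 = scans.ms2
    mz = rec["measured_mz"].to_numpy(dtype=float)
    apex = rec["apex_rt"].to_numpy(dtype=float)
    pw = rec["peak_width"].to_numpy(dtype=float)
    pw = np.where(np.isfinite(pw), pw, rec["fwhm"].to_numpy(dtype=float) * 2.0)
    pw = np.where(np.isfinite(pw), pw, 0.5)  # last-resort default window, minutes
    nmatch = rec["n_ms2_matched"].to_numpy(dtype=float)

    n = len(rec)
    cand_dist: list[list] = [[] for _ in range(n)]
    cand_scan: list[list] = [[] for _ in range(n)]
    scan_rt = ms2["rt"].to_numpy(dtype=float)
    scan_gid = np.arange(len(ms2))
    lo_all = ms2["iso_lo"].to_numpy(dtype=float)
    hi_all = ms2["iso_hi"].to_numpy(dtype=float)
    windows = ms2[["iso_lo", "iso_hi"]].drop_duplicates()
    for lo, hi in windows.itertuples(index=False):
        in_win = (lo_all == lo) & (hi_all == hi)
        w_rt = scan_rt[in_win]
        w_gid = scan_gid[in_win]
        order = np.argsort(w_rt, kind="stable")
        w_rt = w_rt[order]
        w_gid = w_gid[order]
        rec_mask = np.nonzero((mz >= lo) & (mz < hi))[0]
        if rec_mask.size == 0 or w_rt.size == 0:
            continue
        half = pw[rec_mask] / 2.0
        starts = np.searchsorted(w_rt, apex[rec_mask] - half, side="left")
        stops = np.searchsorted(w_rt, apex[rec_mask] + half, side="right")
        for i, a, b in zip(rec_mask, starts, stops):
            if b > a:
                cand_dist[i].extend(np.abs(w_rt[a:b] - apex[i]))
                cand_scan[i].extend(w_gid[a:b])

    counts = np.zeros(n, dtype=int)
    hit_scans: set[int] = set()
    for i in range(n):
        cands = cand_scan[i]
        if not cands:
            continue
        k = len(cands) if not math.isfinite(nmatch[i]) else min(int(nmatch[i]), len(cands))
        if k <= 0:
            continue
        if k < len(cands):
            order = np.argsort(cand_dist[i], kind="stable")[:k]
            chosen = [cands[j] for j in order]
        else:
            chosen = cands
        counts[i] = len(chosen)
        hit_scans.update(chosen)
    return counts, len(hit_scans)


def decompose_dia_score(report: IdentReport, scans: ScanTable) -> DiaScoreDecomposition:
    """Decompose a DIA run's identification outcome into its five factors."""
    n_acquired = len(scans.ms2)
    if n_acquired == 0:
        raise ValueError("scan table contains no MS2 scans")
    counts, n_identified_ms2 = _reconstruct_assignment(report, scans)
    return DiaScoreDecomposition.from_counts(
        n_acquired_ms2=n_acquired,
        n_identified_ms2=n_identified_ms2,
        n_redundant_precursors=int(counts.sum()),
        n_unique_precursors=int((counts > 0).sum()),
    )


def decompose_dda_score(report: IdentReport, scans: ScanTable) -> DdaScoreDecomposition:
    """Decompose a DDA run; every record contributes n_ms2_matched (default 1) scans."""
    n_acquired = len(scans.ms2)
    if n_acquired == 0:
        raise ValueError("scan table contains no MS2 scans")
    nmatch = report.records["n_ms2_matched"].fillna(1).clip(lower=0)
    return DdaScoreDecomposition(
        n_acquired_ms2=n_acquired,
        n_identified_ms2=int(nmatch.sum()),
        n_unique_precursors=int((nmatch > 0).sum()),
    )


# ---------------------------------------------------------------------------
# scan-level metrics


def compute_scan_metrics(scans: ScanTable) -> list[MetricValue]:
    """MS1/MS2 signal, cycle and ion-source stability metrics for one run."""
    run = scans.run_id
    ms1 = scans.ms1
    ms2 = scans.ms2
    out = [
        _mv("n_ms1_scans", run, len(ms1)),
        _mv("n_ms2_scans", run, len(ms2)),
    ]

    ms1_rt = ms1["rt"].to_numpy(dtype=float)
    if len(ms1_rt) >= 2:
        out.append(_mv("median_cycle_time", run, float(np.median(np.diff(ms1_rt)) * 60.0)))
    else:
        out.append(_not_computable("median_cycle_time", run, "fewer than 2 cycles"))

    for level, frame in (("ms1", ms1), ("ms2", ms2)):
        inj = frame["injection_time"].dropna()
        out.append(
            _mv(f"median_injection_time_{level}", run, float(inj.median()))
            if len(inj)
            else _not_computable(f"median_injection_time_{level}", run,
                                 "injection times absent")
        )
        pc = frame["peak_count"].dropna()
        out.append(
            _mv(f"median_peak_count_{level}", run, float(pc.median()))
            if len(pc)
            else _not_computable(f"median_peak_count_{level}", run, "peak counts absent")
        )
        bpi = frame["base_peak_intensity"].dropna()
        bpi = bpi[bpi > 0]
        out.append(
            _mv(f"median_base_peak_intensity_{level}", run, float(np.log10(bpi.median())))
            if len(bpi)
            else _not_computable(f"median_base_peak_intensity_{level}", run,
                                 "base-peak intensities absent")
        )

    inj_all = scans.scans["injection_time"].dropna()
    if len(inj_all):
        frac = float((inj_all >= 0.99 * inj_all.max()).mean())
        out.append(_mv("fraction_scans_at_max_fill", run, frac))
    else:
        out.append(_not_computable("fraction_scans_at_max_fill", run,
                                   "injection times absent"))

    tic = ms1["tic"].dropna().to_numpy(dtype=float)
    if len(tic) >= 2 and tic.mean() > 0:
        out.append(_mv("tic_cv", run, float(100.0 * tic.std(ddof=1) / tic.mean())))
    else:
        out.append(_not_computable("tic_cv", run, "fewer than 2 MS1 TIC values"))
    pos = tic[tic > 0]
    if len(pos) >= 2:
        ratio = pos[1:] / pos[:-1]
        out.append(_mv("tic_jump_count", run, int(((ratio > 10) | (ratio < 0.1)).sum())))
    else:
        out.append(_not_computable("tic_jump_count", run, "fewer than 2 MS1 TIC values"))
    return out


# ---------------------------------------------------------------------------
# identification metrics


def compute_ident_metrics(report: IdentReport,
                          sequence_db: dict[str, str] | None = None
                          ) -> list[MetricValue]:
    """Identification-result and sample metrics for one run.

    ``sequence_db`` optionally maps protein accessions to amino-acid
    sequences; protein sequence coverage is only computable when given.
    """
    run = report.run_id
    rec = report.records
    if rec.empty:
        ids = ["n_precursors", "n_peptides", "n_protein_groups", "missed_cleavage_rate",
               "median_peak_width", "median_fwhm", "median_ms1_mass_accuracy",
               "median_log10_precursor_intensity", "intensity_dynamic_range",
               "mean_protein_sequence_coverage"]
        return [_not_computable(m, run, "empty report") for m in ids]

    out = [
        _mv("n_precursors", run, report.n_precursors),
        _mv("n_peptides", run, report.n_peptides),
        _mv("n_protein_groups", run, report.n_protein_groups),
    ]

    mc = rec["missed_cleavages"].dropna()
    out.append(
        _mv("missed_cleavage_rate", run, float(100.0 * (mc >= 1).mean()))
        if len(mc)
        else _not_computable("missed_cleavage_rate", run, "missed cleavages absent")
    )

    for mid, col in (("median_peak_width", "peak_width"), ("median_fwhm", "fwhm")):
        vals = rec[col].dropna()
        out.append(
            _mv(mid, run, float(vals.median()))
            if len(vals)
            else _not_computable(mid, run, f"{col} column absent")
        )

    ppm = (rec["measured_mz"] - rec["theoretical_mz"]).abs() / rec["theoretical_mz"] * 1e6
    out.append(_mv("median_ms1_mass_accuracy", run, float(ppm.median())))

    inten = rec["precursor_intensity"].dropna()
    inten = inten[inten > 0]
    out.append(
        _mv("median_log10_precursor_intensity", run, float(np.log10(inten.median())))
        if len(inten)
        else _not_computable("median_log10_precursor_intensity", run,
                             "precursor intensities absent")
    )

    prot = rec.groupby("protein_group")["protein_intensity"].first().dropna()
    prot = prot[prot > 0]
    if len(prot) >= 2:
        p1, p99 = np.percentile(prot.to_numpy(dtype=float), [1, 99])
        out.append(_mv("intensity_dynamic_range", run,
                       float(np.log10(p99 / p1)) if p1 > 0 else None))
    else:
        out.append(_not_computable("intensity_dynamic_range", run,
                                   "fewer than 2 protein intensities"))

    if sequence_db:
        out.append(_mv("mean_protein_sequence_coverage", run,
                       _mean_sequence_coverage(rec, sequence_db)))
    else:
        out.append(_not_computable("mean_protein_sequence_coverage", run,
                                   "no sequence database supplied"))
    return out


def _mean_sequence_coverage(rec: pd.DataFrame, sequence_db: dict[str, str]) -> float | None:
    """Naive substring coverage: % of residues covered by identified peptides."""
    coverages = []
    for group, sub in rec.groupby("protein_group"):
        acc = str(group).split(";")[0].strip().upper()
        seq = sequence_db.get(acc)
        if not seq:
            continue
        covered = np.zeros(len(seq), dtype=bool)
        for pep in sub["stripped_sequence"].dropna().unique():
            start = seq.find(str(pep))
            while start >= 0:
                covered[start:start + len(pep)] = True
                start = seq.find(str(pep), start + 1)
        coverages.append(100.0 * covered.mean())
    return float(np.mean(coverages)) if coverages else None


# ---------------------------------------------------------------------------
# chromatography metrics


def compute_chromatography_metrics(report: IdentReport,
                                   scans: ScanTable | None = None,
                                   edge_quantile: float = 0.005
                                   ) -> list[MetricValue]:
    """LC delay/tail time and active-gradient fraction.

    The delay (tail) time is the RT by which the cumulative count of
    identified-precursor apexes reaches ``edge_quantile`` (``1 -
    edge_quantile``) of the total — robust to a single stray early or late
    identification.
    """
    run = report.run_id
    rec = report.records
    ids = ["lc_delay_time", "lc_tail_time", "active_gradient_fraction"]
    if rec.empty:
        return [_not_computable(m, run, "empty report") for m in ids]
    rt = rec["apex_rt"].to_numpy(dtype=float)
    gradient = report.gradient_length
    if gradient is None and scans is not None and len(scans.scans):
        gradient = float(scans.scans["rt"].max())
    if gradient is None:
        gradient = report.effective_gradient_length()
    q_lo, q_hi = np.quantile(rt, [edge_quantile, 1.0 - edge_quantile])
    return [
        _mv("lc_delay_time", run, float(q_lo)),
        _mv("lc_tail_time", run, float(max(gradient - q_hi, 0.0))),
        _mv("active_gradient_fraction", run,
            float(np.clip((q_hi - q_lo) / gradient, 0.0, 1.0)) if gradient > 0 else None),
    ]


def rt_histogram(report: IdentReport, bin_minutes: float = 1.0) -> pd.Series:
    """Identifications per RT bin (index = bin left edge in minutes)."""
    rt = report.records["apex_rt"].to_numpy(dtype=float)
    if len(rt) == 0:
        return pd.Series(dtype=int)
    edges = np.arange(0.0, rt.max() + bin_minutes, bin_minutes)
    counts, _ = np.histogram(rt, bins=edges)
    return pd.Series(counts, index=edges[:-1], name="n_identifications")


# ---------------------------------------------------------------------------
# DIA window metrics


def per_window_precursor_counts(scans: ScanTable, report: IdentReport) -> pd.DataFrame:
    """Precursors assigned to each isolation window (by m/z containment)."""
    win = scans.windows()
    mz = report.records["measured_mz"].to_numpy(dtype=float)
    counts = [
        int(((mz >= lo) & (mz < hi)).sum())
        for lo, hi in win[["iso_lo", "iso_hi"]].itertuples(index=False)
    ]
    win = win.copy()
    win["n_precursors"] = counts
    return win


def compute_window_metrics(scans: ScanTable, report: IdentReport) -> list[MetricValue]:
    run = scans.run_id
    win = scans.windows()
    ids = ["n_windows_per_cycle", "mean_window_width", "window_load_imbalance"]
    if win.empty:
        return [_not_computable(m, run, "no MS2 windows") for m in ids]
    widths = (win["iso_hi"] - win["iso_lo"]).to_numpy(dtype=float)
    out = [
        _mv("n_windows_per_cycle", run, len(win)),
        _mv("mean_window_width", run, float(widths.mean())),
    ]
    counts = per_window_precursor_counts(scans, report)["n_precursors"]
    med = float(counts.median())
    if med > 0:
        out.append(_mv("window_load_imbalance", run, float(counts.max() / med)))
    else:
        out.append(_not_computable("window_load_imbalance", run,
                                   "median per-window precursor count is zero"))
    return out


# ---------------------------------------------------------------------------
# MS1 feature detection


@dataclass
class Ms1Feature:
    """A chromatographic trace linked across consecutive MS1 scans."""

    mz_centroid: float
    rt_start: float
    rt_end: float
    apex_intensity: float
    n_scans: int
    identified: bool = False


def detect_ms1_features(scans: ScanTable, report: IdentReport,
                        ppm_tol: float = 10.0, min_trace_length: int = 3
                        ) -> tuple[list[Ms1Feature], float]:
    """Detect MS1 features by simple trace linking and match them to IDs.

    A feature is a maximal chain of centroids across consecutive MS1 scans
    whose m/z stays within ``ppm_tol`` of the running intensity-weighted
    centroid, with at least ``min_trace_length`` scans.  No isotope
    deconvolution is attempted — each isotopologue trace is its own
    feature.  A feature counts as identified when some report record's
    measured m/z lies within ``ppm_tol`` and its apex RT within the
    feature's RT span.

    Returns the feature list and the identified-feature fraction.
    """
    if not scans.centroids:
        raise ValueError("MS1 centroids are required for feature detection")
    ms1 = scans.ms1
    open_traces: list[dict] = []
    features: list[Ms1Feature] = []

    def close(trace: dict) -> None:
        if trace["n"] >= min_trace_length:
            features.append(Ms1Feature(
                mz_centroid=trace["mz"],
                rt_start=trace["rt_start"],
                rt_end=trace["rt_end"],
                apex_intensity=trace["apex"],
                n_scans=trace["n"],
            ))

    for row in ms1.itertuples():
        cent = scans.centroids.get(int(row.scan_index))
        if cent is None:
            for t in open_traces:
                close(t)
            open_traces = []
            continue
        mzs, ints = cent
        used = np.zeros(len(mzs), dtype=bool)
        still_open: list[dict] = []
        for t in open_traces:
            j = int(np.searchsorted(mzs, t["mz"]))
            best = -1
            best_d = t["mz"] * ppm_tol * 1e-6
            for k in (j - 1, j):
                if 0 <= k < len(mzs) and not used[k]:
                    d = abs(mzs[k] - t["mz"])
                    if d <= best_d:
                        best, best_d = k, d
            if best >= 0:
                used[best] = True
                t["mz"] = (t["mz"] * t["wsum"] + mzs[best] * ints[best]) / (t["wsum"] + ints[best])
                t["wsum"] += ints[best]
                t["rt_end"] = row.rt
                t["apex"] = max(t["apex"], float(ints[best]))
                t["n"] += 1
                still_open.append(t)
            else:
                close(t)
        for k in np.nonzero(~used)[0]:
            still_open.append({
                "mz": float(mzs[k]), "wsum": float(ints[k]),
                "rt_start": float(row.rt), "rt_end": float(row.rt),
                "apex": float(ints[k]), "n": 1,
            })
        open_traces = still_open
    for t in open_traces:
        close(t)

    rec = report.records
    rec_mz = np.sort(rec["measured_mz"].to_numpy(dtype=float))
    order = np.argsort(rec["measured_mz"].to_numpy(dtype=float))
    rec_rt = rec["apex_rt"].to_numpy(dtype=float)[order]
    n_id = 0
    for f in features:
        tol = f.mz_centroid * ppm_tol * 1e-6
        a = np.searchsorted(rec_mz, f.mz_centroid - tol, side="left")
        b = np.searchsorted(rec_mz, f.mz_centroid + tol, side="right")
        if b > a and np.any((rec_rt[a:b] >= f.rt_start) & (rec_rt[a:b] <= f.rt_end)):
            f.identified = True
            n_id += 1
    frac = n_id / len(features) if features else float("nan")
    return features, frac
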