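"""Readers and writers for the delimited report dialects used across the package.

Two tabular inputs drive everything downstream:

* the *identification report* — one row per identified precursor (modified
  sequence + charge) with retention time, peak shape, m/z, intensity and
  q-value columns, plus peptide- and protein-group-level rollups.  The
  canonical header is :data:`IDENT_COLUMNS`; arbitrary vendor dialects are
  supported through :class:`ColumnMap`.
* the *scan table* — one row per MS1/MS2 scan (level, RT, TIC, base-peak
  intensity, peak count, ion injection time, isolation window bounds), a
  plain-text stand-in for converted vendor raw files.  An optional mzML
  adapter maps mzML spectra onto the same records.

Retention times are minutes everywhere; a :class:`ColumnMap` may declare a
source file in seconds and the reader converts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "IDENT_COLUMNS",
    "IDENT_REQUIRED",
    "SCAN_COLUMNS",
    "ColumnMap",
    "IdentReport",
    "ScanTable",
    "ReportError",
    "EmptyFileError",
    "MissingColumnError",
    "ScanOrderError",
    "read_ident_report",
    "read_scan_table",
    "read_scan_table_mzml",
    "read_centroid_sidecar",
    "write_metric_table",
    "read_metric_table",
]

#: canonical identification-report header, in writing order
IDENT_COLUMNS = [
    "run_id",
    "precursor_id",
    "stripped_sequence",
    "charge",
    "measured_mz",
    "theoretical_mz",
    "apex_rt",
    "delta_rt",
    "fwhm",
    "peak_width",
    "missed_cleavages",
    "precursor_intensity",
    "peptide_intensity",
    "protein_group",
    "protein_intensity",
    "q_value",
    "n_ms2_matched",
]

#: columns that must be present (directly or via a ColumnMap)
IDENT_REQUIRED = [
    "run_id",
    "precursor_id",
    "stripped_sequence",
    "charge",
    "measured_mz",
    "theoretical_mz",
    "apex_rt",
    "precursor_intensity",
    "protein_group",
    "protein_intensity",
    "q_value",
]

#: optional columns; absent ones are materialised as missing values
IDENT_OPTIONAL = [c for c in IDENT_COLUMNS if c not in IDENT_REQUIRED]

SCAN_COLUMNS = [
    "scan_index",
    "ms_level",
    "rt",
    "tic",
    "base_peak_intensity",
    "peak_count",
    "injection_time",
    "iso_lo",
    "iso_hi",
]


class ReportError(ValueError):
    """Base class for malformed input files."""


class EmptyFileError(ReportError):
    """File contains no header at all (distinct from header-only)."""


class MissingColumnError(ReportError):
    """A required (mapped) column is absent from the header."""


class ScanOrderError(ReportError):
    """Scan table violates acquisition-order invariants."""


@dataclass
class ColumnMap:
    """Mapping from canonical field names to source header names.

    Parameters
    ----------
    mapping : dict
        ``canonical -> source header``.  Canonical names not listed are
        assumed to appear verbatim in the file.
    delimiter : str
        Field separator of the source file.
    decimal : str
        Decimal mark of the source file ("." or ",").
    rt_unit : str
        "minutes" (default) or "seconds"; RT-like columns (apex_rt,
        delta_rt, fwhm, peak_width) are converted to minutes on read.
    """

    mapping: dict[str, str] = field(default_factory=dict)
    delimiter: str = "\t"
    decimal: str = "."
    rt_unit: str = "minutes"

    def __post_init__(self) -> None:
        if self.rt_unit not in ("minutes", "seconds"):
            raise ValueError(f"rt_unit must be minutes or seconds, got {self.rt_unit!r}")
        targets = list(self.mapping.keys())
        if len(set(targets)) != len(targets):  # pragma: no cover - dict keys unique
            raise ValueError("duplicate canonical names in mapping")
        unknown = set(targets) - set(IDENT_COLUMNS)
        if unknown:
            raise ValueError(f"unknown canonical field(s): {sorted(unknown)}")

    def source_name(self, canonical: str) -> str:
        return self.mapping.get(canonical, canonical)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ColumnMap":
        """Load a column map from a YAML file with the dataclass's fields."""
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(
            mapping=dict(raw.get("mapping", {})),
            delimiter=str(raw.get("delimiter", "\t")),
            decimal=str(raw.get("decimal", ".")),
            rt_unit=str(raw.get("rt_unit", "minutes")),
        )


@dataclass
class IdentReport:
    """One run's validated identification/quantification report.

    Attributes
    ----------
    run_id : str
    records : pandas.DataFrame
        Canonical columns (:data:`IDENT_COLUMNS`), one row per precursor,
        source order preserved.
    gradient_length : float or None
        LC gradient length in minutes; ``None`` means "infer from data".
    n_dropped : int
        Rows discarded during validation.
    """

    run_id: str
    records: pd.DataFrame
    gradient_length: float | None = None
    n_dropped: int = 0

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_precursors(self) -> int:
        return len(self.records)

    @property
    def n_peptides(self) -> int:
        return int(self.records["stripped_sequence"].nunique())

    @property
    def n_protein_groups(self) -> int:
        return int(self.records["protein_group"].nunique())

    def effective_gradient_length(self) -> float:
        if self.gradient_length is not None:
            return float(self.gradient_length)
        if len(self.records) == 0:
            return float("nan")
        return float(np.ceil(self.records["apex_rt"].max()))


@dataclass
class ScanTable:
    """One run's per-scan acquisition records.

    ``scans`` carries :data:`SCAN_COLUMNS` plus a derived ``cycle`` column
    (a cycle = one MS1 scan and the MS2 scans that follow it until the next
    MS1).  ``centroids`` optionally maps scan_index -> (mz, intensity)
    arrays sorted by m/z.
    """

    run_id: str
    scans: pd.DataFrame
    centroids: dict[int, tuple[np.ndarray, np.ndarray]] | None = None

    @property
    def ms1(self) -> pd.DataFrame:
        return self.scans[self.scans["ms_level"] == 1]

    @property
    def ms2(self) -> pd.DataFrame:
        return self.scans[self.scans["ms_level"] == 2]

    @property
    def n_cycles(self) -> int:
        return int(self.scans["cycle"].max()) + 1 if len(self.scans) else 0

    def windows(self) -> pd.DataFrame:
        """Isolation-window set of the first full cycle, ordered by iso_lo."""
        ms2 = self.ms2
        if ms2.empty:
            return pd.DataFrame(columns=["iso_lo", "iso_hi"])
        first = ms2[ms2["cycle"] == ms2["cycle"].iloc[0]]
        return (
            first[["iso_lo", "iso_hi"]]
            .drop_duplicates()
            .sort_values("iso_lo")
            .reset_index(drop=True)
        )


# ---------------------------------------------------------------------------
# identification report


def _read_delimited(path: str | Path, delimiter: str, decimal: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise EmptyFileError(f"{path} is empty (no header)")
    return pd.read_csv(path, sep=delimiter, decimal=decimal)


_RT_COLUMNS = ["apex_rt", "delta_rt", "fwhm", "peak_width"]
_NUMERIC_COLUMNS = [
    "charge",
    "measured_mz",
    "theoretical_mz",
    "apex_rt",
    "delta_rt",
    "fwhm",
    "peak_width",
    "missed_cleavages",
    "precursor_intensity",
    "peptide_intensity",
    "protein_intensity",
    "q_value",
    "n_ms2_matched",
]


def read_ident_report(
    path: str | Path,
    column_map: ColumnMap | None = None,
    gradient_length: float | None = None,
) -> IdentReport:
    """Read and validate one identification report.

    Rows violating record invariants (negative intensity, q-value outside
    [0, 1], charge < 1, fwhm > peak_width, duplicated precursor_id, ...)
    are dropped and counted in ``IdentReport.n_dropped``.  A missing
    *required* column raises :class:`MissingColumnError` naming it.
    """
    cmap = column_map or ColumnMap()
    df = _read_delimited(path, cmap.delimiter, cmap.decimal)

    rename = {}
    for canonical in IDENT_COLUMNS:
        src = cmap.source_name(canonical)
        if src in df.columns:
            rename[src] = canonical
        elif canonical in IDENT_REQUIRED:
            raise MissingColumnError(
                f"required column {canonical!r} (source header {src!r}) missing from {path}"
            )
    df = df.rename(columns=rename)
    for canonical in IDENT_OPTIONAL:
        if canonical not in df.columns:
            df[canonical] = np.nan
    df = df[IDENT_COLUMNS]

    for col in _NUMERIC_COLUMNS:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    if cmap.rt_unit == "seconds":
        df[_RT_COLUMNS] = df[_RT_COLUMNS] / 60.0

    n_before = len(df)
    ok = (
        df["precursor_id"].notna()
        & df["charge"].notna()
        & (df["charge"] >= 1)
        & (df["apex_rt"] >= 0)
        & df["q_value"].between(0.0, 1.0)
        & (df["measured_mz"] > 0)
        & (df["theoretical_mz"] > 0)
        & ~(df["precursor_intensity"] < 0)
        & ~(df["peptide_intensity"] < 0)
        & ~(df["protein_intensity"] < 0)
        & ~(df["missed_cleavages"] < 0)
        & ~(df["n_ms2_matched"] < 0)
        & ~(df["fwhm"] > df["peak_width"])
    )
    df = df[ok]
    df = df[~df["precursor_id"].duplicated(keep="first")]
    n_dropped = n_before - len(df)
    df = df.reset_index(drop=True)

    run_id = str(df["run_id"].iloc[0]) if len(df) else Path(path).stem
    return IdentReport(
        run_id=run_id,
        records=df,
        gradient_length=gradient_length,
        n_dropped=n_dropped,
    )


# ---------------------------------------------------------------------------
# scan table


def _finalize_scan_table(df: pd.DataFrame, run_id: str,
                         centroids=None) -> ScanTable:
    rt = df["rt"].to_numpy(dtype=float)
    if len(rt) > 1:
        dec = np.nonzero(np.diff(rt) < 0)[0]
        if dec.size:
            bad = int(df["scan_index"].iloc[dec[0] + 1])
            raise ScanOrderError(f"retention time decreases at scan_index {bad}")
    levels = df["ms_level"].to_numpy(dtype=int)
    if not np.isin(levels, (1, 2)).all():
        raise ScanOrderError("ms_level must be 1 or 2")
    if len(levels) and levels[0] != 1:
        raise ScanOrderError("MS2 scan before any MS1 scan")
    ms2 = levels == 2
    if ms2.any():
        lo = df.loc[ms2, "iso_lo"].to_numpy(dtype=float)
        hi = df.loc[ms2, "iso_hi"].to_numpy(dtype=float)
        if np.isnan(lo).any() or np.isnan(hi).any() or (lo >= hi).any():
            raise ScanOrderError("MS2 scans require iso_lo < iso_hi")
    df = df.copy()
    df["cycle"] = np.cumsum(levels == 1) - 1

    table = ScanTable(run_id=run_id, scans=df.reset_index(drop=True), centroids=centroids)
    _warn_on_varying_windows(table)
    return table


def _warn_on_varying_windows(table: ScanTable) -> None:
    ms2 = table.ms2
    if ms2.empty:
        return
    per_cycle = ms2.groupby("cycle").apply(
        lambda g: tuple(sorted(zip(g["iso_lo"], g["iso_hi"]))), include_groups=False
    )
    full = per_cycle[per_cycle.index < per_cycle.index.max()]  # last cycle may be truncated
    if full.nunique() > 1:
        warnings.warn(
            f"run {table.run_id}: isolation-window set varies across cycles",
            UserWarning,
            stacklevel=3,
        )


def read_scan_table(
    path: str | Path,
    run_id: str | None = None,
    delimiter: str = "\t",
    centroid_path: str | Path | None = None,
) -> ScanTable:
    """Read one run's scan table (canonical TSV dialect).

    RT must be non-decreasing with scan_index and the first scan must be
    MS1; violations raise :class:`ScanOrderError` naming the first
    offending scan_index.
    """
    df = _read_delimited(path, delimiter, ".")
    missing = [c for c in SCAN_COLUMNS if c not in df.columns]
    if missing:
        raise MissingColumnError(f"scan table missing column(s) {missing} in {path}")
    df = df[SCAN_COLUMNS]
    centroids = read_centroid_sidecar(centroid_path) if centroid_path else None
    return _finalize_scan_table(df, run_id or Path(path).stem, centroids)


def scan_table_from_frame(df: pd.DataFrame, run_id: str, centroids=None) -> ScanTable:
    """Build a validated ScanTable from an in-memory frame (generator path)."""
    return _finalize_scan_table(df[SCAN_COLUMNS], run_id, centroids)


def read_centroid_sidecar(path: str | Path) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    """Read a per-scan centroid sidecar (scan_index, mz, intensity TSV)."""
    df = _read_delimited(path, "\t", ".")
    out: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for idx, grp in df.groupby("scan_index"):
        grp = grp.sort_values("mz")
        out[int(idx)] = (
            grp["mz"].to_numpy(dtype=float),
            grp["intensity"].to_numpy(dtype=float),
        )
    return out


_MZML_NS = "{http://psi.hupo.org/ms/mzml}"


def _cvparams(elem) -> dict[str, str]:
    return {
        cv.get("name"): cv.get("value", "")
        for cv in elem.findall(f"{_MZML_NS}cvParam")
    }


def _decode_binary_array(array_elem) -> np.ndarray:
    import base64
    import zlib

    params = _cvparams(array_elem)
    raw = base64.b64decode(array_elem.findtext(f"{_MZML_NS}binary") or "")
    if "zlib compression" in params:
        raw = zlib.decompress(raw)
    dtype = np.float32 if "32-bit float" in params else np.float64
    return np.frombuffer(raw, dtype=dtype).astype(float)


def read_scan_table_mzml(path: str | Path, run_id: str | None = None,
                         load_centroids: bool = False) -> ScanTable:
    """mzML adapter: map mzML spectra 1:1 onto scan records.

    A lightweight reader for the scan-level subset this package needs (ms
    level, scan start time, TIC, base-peak intensity, injection time,
    isolation window, and optionally MS1 peak arrays); it does not cover
    the full mzML controlled vocabulary.
    """
    from xml.etree import ElementTree

    rows = []
    centroids: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    i = 0
    for _, spec in ElementTree.iterparse(str(path)):
        if spec.tag != f"{_MZML_NS}spectrum":
            continue
        i += 1
        sp = _cvparams(spec)
        level = int(sp.get("ms level", 1))
        scan = spec.find(f"{_MZML_NS}scanList/{_MZML_NS}scan")
        sc = _cvparams(scan) if scan is not None else {}
        rt = float(sc.get("scan start time", "nan"))
        rt_cv = None if scan is None else next(
            (cv for cv in scan.findall(f"{_MZML_NS}cvParam")
             if cv.get("name") == "scan start time"), None)
        if rt_cv is not None and "second" in (rt_cv.get("unitName") or "minute"):
            rt /= 60.0
        iso_lo = iso_hi = np.nan
        if level == 2:
            iso = spec.find(f"{_MZML_NS}precursorList/{_MZML_NS}precursor/"
                            f"{_MZML_NS}isolationWindow")
            if iso is not None:
                ip = _cvparams(iso)
                target = float(ip.get("isolation window target m/z", "nan"))
                iso_lo = target - float(ip.get("isolation window lower offset", 0.0))
                iso_hi = target + float(ip.get("isolation window upper offset", 0.0))
        n_peaks = int(spec.get("defaultArrayLength", 0))
        mz_arr = inten_arr = None
        if load_centroids and level == 1:
            for arr in spec.findall(f"{_MZML_NS}binaryDataArrayList/"
                                    f"{_MZML_NS}binaryDataArray"):
                ap = _cvparams(arr)
                if "m/z array" in ap:
                    mz_arr = _decode_binary_array(arr)
                elif "intensity array" in ap:
                    inten_arr = _decode_binary_array(arr)
        rows.append({
            "scan_index": i,
            "ms_level": level,
            "rt": rt,
            "tic": float(sp.get("total ion current", "nan")),
            "base_peak_intensity": float(sp.get("base peak intensity", "nan")),
            "peak_count": n_peaks,
            "injection_time": float(sc.get("ion injection time", "nan")),
            "iso_lo": iso_lo,
            "iso_hi": iso_hi,
        })
        if mz_arr is not None and inten_arr is not None and len(mz_arr):
            order = np.argsort(mz_arr)
            centroids[i] = (mz_arr[order], inten_arr[order])
        spec.clear()
    df = pd.DataFrame(rows, columns=SCAN_COLUMNS)
    return _finalize_scan_table(df, run_id or Path(path).stem,
                                centroids if load_centroids else None)


# ---------------------------------------------------------------------------
# metric tables


def write_metric_table(metrics: Iterable, path: str | Path) -> Path:
    """Write metric values to a tab-delimited file.

    One row per (run_id, metric_id) with columns value, score, flag,
    computable and reason; round-trips through :func:`read_metric_table`
    losslessly at 6 significant digits.  ``metrics`` may be MetricValue
    objects or mappings with the same keys.
    """
    rows = []
    for m in metrics:
        get = m.get if isinstance(m, Mapping) else lambda k, d=None, m=m: getattr(m, k, d)
        rows.append(
            {
                "run_id": get("run_id"),
                "metric_id": get("metric_id"),
                "value": get("value"),
                "score": get("score"),
                "flag": get("flag"),
                "computable": get("computable", True),
                "reason": get("reason", "") or "",
            }
        )
    if not rows:
        raise ValueError("no metrics to write")
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path


def read_metric_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["reason"] = df["reason"].fillna("")
    return df
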