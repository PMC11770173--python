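"""Shared builders for toy identification reports and scan tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from cohortqc.report_io import (
    IDENT_COLUMNS,
    SCAN_COLUMNS,
    IdentReport,
    scan_table_from_frame,
)


def make_ident_frame(n: int, run_id: str = "R00", seed: int = 0, **overrides
                     ) -> pd.DataFrame:
    """A valid canonical identification frame with n rows."""
    rng = np.random.default_rng(seed)
    mz = rng.uniform(400.0, 1100.0, n)
    df = pd.DataFrame({
        "run_id": run_id,
        "precursor_id": [f"PEP{i:05d}K.2" for i in range(n)],
        "stripped_sequence": [f"PEP{i:05d}K" for i in range(n)],
        "charge": 2,
        "measured_mz": mz,
        "theoretical_mz": mz,
        "apex_rt": np.sort(rng.uniform(2.0, 28.0, n)),
        "delta_rt": rng.normal(0.0, 0.05, n),
        "fwhm": np.full(n, 0.2),
        "peak_width": np.full(n, 0.34),
        "missed_cleavages": 0,
        "precursor_intensity": rng.lognormal(14.0, 1.0, n),
        "peptide_intensity": rng.lognormal(14.0, 1.0, n),
        "protein_group": [f"PROT{i // 4:04d}" for i in range(n)],
        "protein_intensity": rng.lognormal(16.0, 1.0, n),
        "q_value": 0.001,
        "n_ms2_matched": 3,
    })[IDENT_COLUMNS]
    for col, val in overrides.items():
        df[col] = val
    return df


def make_report(n: int = 20, run_id: str = "R00", seed: int = 0,
                gradient_length: float | None = 30.0, **overrides) -> IdentReport:
    return IdentReport(run_id=run_id, records=make_ident_frame(n, run_id, seed, **overrides),
                       gradient_length=gradient_length)


def make_scan_frame(n_cycles: int = 5, n_windows: int = 4,
                    cycle_time_min: float = 0.05,
                    mz_range: tuple[float, float] = (350.0, 1200.0),
                    tic_ms1: float | np.ndarray = 1e9,
                    injection_ms1: float = 5.0,
                    injection_ms2: float = 20.0) -> pd.DataFrame:
    edges = np.linspace(mz_range[0], mz_range[1], n_windows + 1)
    n_per = n_windows + 1
    slot = np.tile(np.arange(n_per), n_cycles)
    cyc = np.repeat(np.arange(n_cycles), n_per)
    is_ms1 = slot == 0
    win = np.where(is_ms1, 0, slot - 1)
    tic1 = np.broadcast_to(np.atleast_1d(tic_ms1), (n_cycles,))
    df = pd.DataFrame({
        "scan_index": np.arange(1, n_cycles * n_per + 1),
        "ms_level": np.where(is_ms1, 1, 2),
        "rt": cyc * cycle_time_min + slot * (cycle_time_min / n_per),
        "tic": np.where(is_ms1, tic1[cyc], 2e7),
        "base_peak_intensity": np.where(is_ms1, 1e8, 2e6),
        "peak_count": np.where(is_ms1, 1500, 200),
        "injection_time": np.where(is_ms1, injection_ms1, injection_ms2),
        "iso_lo": np.where(is_ms1, np.nan, edges[win]),
        "iso_hi": np.where(is_ms1, np.nan, edges[win + 1]),
    })[SCAN_COLUMNS]
    return df


def make_scan_table(run_id: str = "R00", **kwargs):
    return scan_table_from_frame(make_scan_frame(**kwargs), run_id)


@pytest.fixture
def toy_report():
    return make_report(40)


@pytest.fixture
def toy_scans():
    return make_scan_table(n_cycles=10, n_windows=4)
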