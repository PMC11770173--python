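"""Reproducible synthetic LC-MS cohorts with known ground truth.

The generator emulates a controlled QC cohort: every run re-measures a
shared latent precursor catalogue (log-normal intensities, a common RT
catalogue plus per-run jitter) under bounded run-to-run variation, and
anomalies of four kinds can be planted in chosen runs:

* ``contamination`` — a contaminant panel is injected at a target fraction
  of total intensity under a *replacement* model (fixed column load:
  everything else is scaled down by ``1 - magnitude``);
* ``rt_drift`` — a constant RT shift in minutes;
* ``intensity_drop`` — all intensities attenuated ``magnitude``-fold;
* ``low_id_rate`` — identifications subsampled to a ``magnitude`` fraction,
  preferentially losing low-intensity precursors (identification failure
  concentrates at low S/N).

Run-level nuisance effects (intensity scale, RT shift, detection
efficiency) are drawn from *uniform* distributions: a well-behaved QC
cohort drifts within bounds, and bounded nulls are what makes a 2-SD flag
a genuine anomaly signal rather than a tail event.

``worked_example_fixture`` builds two deterministic single runs whose
precursor-to-scan assignment reproduces, exactly, the canonical
narrow-window (80 x ~6 Th; complexity 2.27, duplicate rate 1.58) and
wide-window (22 x ~26 Th; complexity 4.1, duplicate rate 4.07) DIA
operating points used to discuss MS2 utilization.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .report_io import IDENT_COLUMNS, SCAN_COLUMNS, IdentReport, ScanTable, \
    scan_table_from_frame

__all__ = [
    "Anomaly",
    "CohortConfig",
    "CohortData",
    "generate_cohort",
    "write_cohort",
    "worked_example_fixture",
    "assignment_run",
]

_AA = np.array(list("ACDEFGHILMNPQSTVWY"))
_MS2_DWELL_S = 0.05  # per-scan time, seconds; cycle = (n_windows + 1) * dwell


@dataclass(frozen=True)
class Anomaly:
    """A planted anomaly: which run, what kind, how strong.

    ``magnitude`` semantics by kind: contamination — target contaminant
    intensity fraction; rt_drift — minutes; intensity_drop — fold
    attenuation; low_id_rate — retained identification fraction.
    """

    run_index: int
    kind: str
    magnitude: float
    panel: str = "erythrocyte"

    def __post_init__(self) -> None:
        if self.kind not in ("contamination", "rt_drift", "intensity_drop", "low_id_rate"):
            raise ValueError(f"unknown anomaly kind {self.kind!r}")


#: small baseline presence of each default panel (fraction of total intensity)
_BASELINE_PANEL_FRACTION = {
    "erythrocyte": 0.006,
    "cellular_debris": 0.010,
    "serum_high_abundance": 0.014,
}
_PANEL_MEMBERS = {
    "erythrocyte": ["HBB", "HBA1", "CA1"],
    "cellular_debris": ["KRT1", "ACTB", "GAPDH"],
    "serum_high_abundance": ["ALB", "TF", "HP"],
}


@dataclass
class CohortConfig:
    """Study conditions of a synthetic cohort."""

    n_runs: int = 20
    n_proteins: int = 300
    peptides_per_protein_mean: float = 3.0
    gradient_length: float = 30.0       # minutes
    n_windows: int = 40
    mz_range: tuple[float, float] = (350.0, 1200.0)
    log2_intensity_mean: float = 20.0
    log2_intensity_sd: float = 2.0
    noise_log2_sd: float = 0.20         # per precursor, per run
    noise_sd_jitter: float = 0.05       # uniform(+/-) per-run noise level
    run_effect_log2: float = 0.25       # uniform(+/-) run intensity scale
    spread_jitter: float = 0.06         # uniform(+/-) run dynamic-range factor
    run_rt_shift_max: float = 0.10      # uniform(+/-) run RT shift, minutes
    rt_jitter_sd: float = 0.05          # per precursor RT jitter, minutes
    detect_rate: float = 0.93           # baseline identification fraction
    detect_rate_jitter: float = 0.03    # uniform(+/-) per run
    panel_effect_log2: float = 0.5      # uniform(+/-) per panel per run
    q_ms2_target: float = 0.75
    anomalies: list[Anomaly] = field(default_factory=list)
    seed: int = 0
    with_scans: bool = True

    def __post_init__(self) -> None:
        for a in self.anomalies:
            if not 0 <= a.run_index < self.n_runs:
                raise ValueError(f"anomaly run_index {a.run_index} out of range")
        if not 0 < self.detect_rate <= 1:
            raise ValueError("detect_rate must be in (0, 1]")
        width = (self.mz_range[1] - self.mz_range[0]) / self.n_windows
        if width <= 1.0:
            raise ValueError("infeasible window/mz combination: windows narrower than 1 Th")


@dataclass
class CohortData:
    reports: list[IdentReport]
    scan_tables: list[ScanTable] | None
    ground_truth: dict


def _random_sequences(rng: np.random.Generator, n: int) -> list[str]:
    seqs = []
    seen = set()
    while len(seqs) < n:
        length = int(rng.integers(8, 16))
        s = "".join(rng.choice(_AA, size=length)) + ("K" if rng.random() < 0.5 else "R")
        if s not in seen:
            seen.add(s)
            seqs.append(s)
    return seqs


@dataclass
class _Catalogue:
    prot_names: np.ndarray        # per protein
    pep_protein: np.ndarray       # protein index per peptide
    pep_seq: list[str]
    prec_pep: np.ndarray          # peptide index per precursor
    prec_charge: np.ndarray
    prec_id: np.ndarray
    prec_base_log2: np.ndarray
    prec_theo_mz: np.ndarray
    prec_rt: np.ndarray
    prec_fwhm: np.ndarray
    prec_missed: np.ndarray
    prec_detect_u: np.ndarray     # fixed detectability rank in [0, 1)
    panel_protein_idx: dict[str, np.ndarray]


def _build_catalogue(cfg: CohortConfig, rng: np.random.Generator) -> _Catalogue:
    panel_names = [m for members in _PANEL_MEMBERS.values() for m in members]
    n_prot = cfg.n_proteins + len(panel_names)
    prot_names = np.array(
        [f"PROT{i:04d}" for i in range(cfg.n_proteins)] + panel_names
    )
    prot_base = rng.normal(cfg.log2_intensity_mean, cfg.log2_intensity_sd, n_prot)

    # pin each contaminant panel's expected share of total intensity
    total_regular = float(np.sum(2.0 ** prot_base[: cfg.n_proteins]))
    idx = cfg.n_proteins
    panel_idx: dict[str, np.ndarray] = {}
    for panel, members in _PANEL_MEMBERS.items():
        k = len(members)
        target = _BASELINE_PANEL_FRACTION[panel] * total_regular
        shares = rng.dirichlet(np.full(k, 6.0)) * target
        prot_base[idx:idx + k] = np.log2(shares)
        panel_idx[panel] = np.arange(idx, idx + k)
        idx += k

    n_pep_per_prot = 1 + rng.poisson(max(cfg.peptides_per_protein_mean - 1.0, 0.0), n_prot)
    # contaminant markers are high-abundance proteins with many peptides
    n_pep_per_prot[cfg.n_proteins:] = max(10, int(3 * cfg.peptides_per_protein_mean))
    pep_protein = np.repeat(np.arange(n_prot), n_pep_per_prot)
    n_pep = len(pep_protein)
    pep_seq = _random_sequences(rng, n_pep)
    # split each protein's intensity across its peptides
    pep_log2 = np.empty(n_pep)
    start = 0
    for p in range(n_prot):
        k = n_pep_per_prot[p]
        shares = rng.dirichlet(np.full(k, 3.0))
        pep_log2[start:start + k] = prot_base[p] + np.log2(shares)
        start += k

    second = rng.random(n_pep) < 0.25
    base_charge = rng.choice([2, 3], n_pep, p=[0.7, 0.3])
    base_charge[second] = 2  # the extra charge state is always 3
    prec_pep = np.concatenate([np.arange(n_pep), np.nonzero(second)[0]])
    order = np.argsort(prec_pep, kind="stable")
    prec_pep = prec_pep[order]
    is_second = np.concatenate(
        [np.zeros(n_pep, bool), np.ones(int(second.sum()), bool)]
    )[order]
    n_prec = len(prec_pep)
    prec_charge = np.where(is_second, 3, base_charge[prec_pep])
    prec_base = pep_log2[prec_pep] - np.where(is_second, 1.5, 0.0)
    prec_id = np.array(
        [f"{pep_seq[p]}.{c}" for p, c in zip(prec_pep, prec_charge)]
    )
    lo, hi = cfg.mz_range
    theo = rng.uniform(lo, hi - 1e-6, n_prec)
    rt = rng.uniform(0.065 * cfg.gradient_length, 0.935 * cfg.gradient_length, n_prec)
    fwhm = np.clip(rng.normal(0.25, 0.04, n_prec), 0.10, None)
    pep_missed = (rng.random(n_pep) < 0.12).astype(int)
    detect_u = rng.uniform(0.0, 1.0, n_prec)
    return _Catalogue(
        prot_names=prot_names,
        pep_protein=pep_protein,
        pep_seq=pep_seq,
        prec_pep=prec_pep,
        prec_charge=prec_charge,
        prec_id=prec_id,
        prec_base_log2=prec_base,
        prec_theo_mz=theo,
        prec_rt=rt,
        prec_fwhm=fwhm,
        prec_missed=pep_missed[prec_pep],
        prec_detect_u=detect_u,
        panel_protein_idx=panel_idx,
    )


def _low_id_keep_mask(x_log2: np.ndarray, frac: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Bernoulli retention with logistic intensity weighting, mean ~= frac."""
    z = (x_log2 - x_log2.mean()) / max(x_log2.std(), 1e-9)

    def mean_keep(t: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(-(z - t) / 0.5)))) - frac

    t = brentq(mean_keep, -50.0, 50.0)
    p = 1.0 / (1.0 + np.exp(-(z - t) / 0.5))
    return rng.random(len(z)) < p


def generate_cohort(config: CohortConfig) -> CohortData:
    """Generate one cohort; a fixed seed yields byte-identical outputs."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    cat = _build_catalogue(cfg, rng)
    n_prec = len(cat.prec_id)
    cycle_time_min = (cfg.n_windows + 1) * _MS2_DWELL_S / 60.0
    anomalies_by_run: dict[int, list[Anomaly]] = {}
    for a in cfg.anomalies:
        anomalies_by_run.setdefault(a.run_index, []).append(a)

    prot_of_prec = cat.pep_protein[cat.prec_pep]
    reports: list[IdentReport] = []
    scan_tables: list[ScanTable] | None = [] if cfg.with_scans else None
    truth_runs = {}

    base_center = float(cat.prec_base_log2.mean())
    for r in range(cfg.n_runs):
        run_id = f"R{r:02d}"
        # run-level nuisance effects: bounded (uniform) drift of intensity
        # scale, dynamic range, noise level, RT and detection efficiency
        run_eff = rng.uniform(-cfg.run_effect_log2, cfg.run_effect_log2)
        spread = 1.0 + rng.uniform(-cfg.spread_jitter, cfg.spread_jitter)
        noise_sd = cfg.noise_log2_sd + rng.uniform(-cfg.noise_sd_jitter,
                                                   cfg.noise_sd_jitter)
        run_shift = rng.uniform(-cfg.run_rt_shift_max, cfg.run_rt_shift_max)
        rate = cfg.detect_rate + rng.uniform(-cfg.detect_rate_jitter,
                                             cfg.detect_rate_jitter)

        x = cat.prec_base_log2 + rng.normal(0.0, noise_sd, n_prec)
        x = base_center + (x - base_center) * spread + run_eff
        # contamination load is a sample property: one bounded effect per panel
        for members in cat.panel_protein_idx.values():
            panel_eff = rng.uniform(-cfg.panel_effect_log2, cfg.panel_effect_log2)
            x[np.isin(prot_of_prec, members)] += panel_eff
        apex = cat.prec_rt + run_shift + rng.normal(0.0, cfg.rt_jitter_sd, n_prec)
        apex = np.clip(apex, 0.0, cfg.gradient_length)
        delta = apex - cat.prec_rt
        fwhm = cat.prec_fwhm * (1.0 + rng.normal(0.0, 0.05, n_prec))
        fwhm = np.clip(fwhm, 0.05, None)
        # detection is detectability-ranked: a run identifies the precursors
        # whose fixed detectability rank falls below its efficiency
        keep = cat.prec_detect_u < min(rate, 1.0)

        applied = []
        for a in anomalies_by_run.get(r, []):
            if a.kind == "rt_drift":
                apex = np.clip(apex + a.magnitude, 0.0, None)
                delta = delta + a.magnitude
            elif a.kind == "intensity_drop":
                x = x - np.log2(a.magnitude)
            elif a.kind == "low_id_rate":
                keep &= _low_id_keep_mask(x, a.magnitude, rng)
            elif a.kind == "contamination":
                lin = np.where(keep, 2.0 ** x, 0.0)
                total = lin.sum()
                members = cat.panel_protein_idx[a.panel]
                in_panel = np.isin(prot_of_prec, members)
                csum = lin[in_panel].sum()
                rest = total - csum
                if csum > 0 and rest > 0:
                    x = x + np.where(
                        in_panel,
                        np.log2(a.magnitude * total / csum),
                        np.log2((1.0 - a.magnitude) * total / rest),
                    )
            applied.append({"kind": a.kind, "magnitude": a.magnitude,
                            "panel": a.panel if a.kind == "contamination" else None})
        truth_runs[run_id] = applied

        lin = 2.0 ** x
        ki = np.nonzero(keep)[0]
        pep_sum = np.zeros(len(cat.pep_seq))
        np.add.at(pep_sum, cat.prec_pep[ki], lin[ki])
        prot_sum = np.zeros(len(cat.prot_names))
        np.add.at(prot_sum, prot_of_prec[ki], lin[ki])

        half_w = fwhm * 1.7 / 2.0
        n_scans_matched = (
            np.floor((apex + half_w) / cycle_time_min)
            - np.ceil((apex - half_w) / cycle_time_min)
            + 1
        ).clip(1).astype(int)

        df = pd.DataFrame({
            "run_id": run_id,
            "precursor_id": cat.prec_id[ki],
            "stripped_sequence": [cat.pep_seq[p] for p in cat.prec_pep[ki]],
            "charge": cat.prec_charge[ki],
            "measured_mz": cat.prec_theo_mz[ki]
            * (1.0 + rng.normal(0.0, 1.0, len(ki)) * 1e-6),
            "theoretical_mz": cat.prec_theo_mz[ki],
            "apex_rt": apex[ki],
            "delta_rt": delta[ki],
            "fwhm": fwhm[ki],
            "peak_width": fwhm[ki] * 1.7,
            "missed_cleavages": cat.prec_missed[ki],
            "precursor_intensity": lin[ki],
            "peptide_intensity": pep_sum[cat.prec_pep[ki]],
            "protein_group": cat.prot_names[prot_of_prec[ki]],
            "protein_intensity": prot_sum[prot_of_prec[ki]],
            "q_value": rng.uniform(0.0, 0.01, len(ki)),
            "n_ms2_matched": n_scans_matched[ki],
        })[IDENT_COLUMNS]
        reports.append(IdentReport(run_id=run_id, records=df,
                                   gradient_length=cfg.gradient_length))
        if cfg.with_scans:
            scan_tables.append(_generate_scan_table(cfg, rng, run_id))

    truth = {
        "anomalies": truth_runs,
        "anomalous_runs": sorted({f"R{a.run_index:02d}" for a in cfg.anomalies}),
        "config": {k: v for k, v in asdict(cfg).items() if k != "anomalies"},
    }
    return CohortData(reports=reports, scan_tables=scan_tables, ground_truth=truth)


def _generate_scan_table(cfg: CohortConfig, rng: np.random.Generator,
                         run_id: str) -> ScanTable:
    cycle_time = (cfg.n_windows + 1) * _MS2_DWELL_S / 60.0
    n_cycles = int(cfg.gradient_length / cycle_time)
    lo, hi = cfg.mz_range
    edges = np.linspace(lo, hi, cfg.n_windows + 1)
    n_per_cycle = cfg.n_windows + 1
    n_scans = n_cycles * n_per_cycle

    slot = np.tile(np.arange(n_per_cycle), n_cycles)
    cyc = np.repeat(np.arange(n_cycles), n_per_cycle)
    rt = cyc * cycle_time + slot * (_MS2_DWELL_S / 60.0)
    is_ms1 = slot == 0
    win = np.where(is_ms1, -1, slot - 1)

    # smooth elution hump plus mild lognormal noise
    profile = 0.4 + np.sin(np.clip(rt / cfg.gradient_length, 0, 1) * math.pi)
    tic = np.where(is_ms1, 2e9, 4e7) * profile * np.exp(rng.normal(0.0, 0.05, n_scans))
    base_peak = tic * np.where(is_ms1, 0.08, 0.12)
    peak_count = np.where(is_ms1, rng.poisson(1500, n_scans), rng.poisson(220, n_scans))
    injection = np.where(
        is_ms1, rng.uniform(2.0, 10.0, n_scans), rng.uniform(15.0, 28.0, n_scans)
    )
    df = pd.DataFrame({
        "scan_index": np.arange(1, n_scans + 1),
        "ms_level": np.where(is_ms1, 1, 2),
        "rt": rt,
        "tic": tic,
        "base_peak_intensity": base_peak,
        "peak_count": peak_count,
        "injection_time": injection,
        "iso_lo": np.where(is_ms1, np.nan, edges[np.clip(win, 0, None)]),
        "iso_hi": np.where(is_ms1, np.nan, edges[np.clip(win, 0, None) + 1]),
    })[SCAN_COLUMNS]
    return scan_table_from_frame(df, run_id)


def write_cohort(data: CohortData, out_dir: str | Path) -> Path:
    """Write a cohort to TSV files plus a ground-truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for rep in data.reports:
        rep.records.to_csv(out / f"{rep.run_id}.report.tsv", sep="\t",
                           index=False, float_format="%.8g")
    if data.scan_tables:
        for st in data.scan_tables:
            st.scans[SCAN_COLUMNS].to_csv(out / f"{st.run_id}.scans.tsv", sep="\t",
                                          index=False, float_format="%.8g")
    (out / "ground_truth.json").write_text(
        json.dumps(data.ground_truth, indent=1, sort_keys=True)
    )
    return out


# ---------------------------------------------------------------------------
# worked-example fixtures


def _split_total(total: int, parts: int) -> np.ndarray:
    base, extra = divmod(total, parts)
    out = np.full(parts, base, dtype=int)
    out[:extra] += 1
    return out


def _window_intervals(u: int, s: int, r: int) -> list[tuple[int, int]]:
    """u RT intervals over cycles [0, s) with total length r covering all s.

    Requires u >= s and r >= u; starts from a singleton tiling plus extra
    singletons at cycle 0, then greedily lengthens intervals.
    """
    assert u >= s >= 1 and u <= r <= u * s
    iv = [[c, c + 1] for c in range(s)] + [[0, 1] for _ in range(u - s)]
    extra = r - u
    k = 0
    stalled = 0
    while extra > 0:
        a, b = iv[k]
        take = min(s - b, extra)
        if take > 0:
            iv[k][1] += take
            extra -= take
            stalled = 0
        else:
            stalled += 1
            if stalled > len(iv):  # all intervals at full length
                raise ValueError("redundant load exceeds window capacity")
        k = (k + 1) % len(iv)
    return [tuple(x) for x in iv]


_WORKED_EXAMPLES = {
    # unique precursors, identified MS2 scans, redundant identifications
    "win80": {"n_windows": 80, "unique": 11350, "identified": 7900, "redundant": 17933},
    "win22": {"n_windows": 22, "unique": 4100, "identified": 4070, "redundant": 16687},
}


def worked_example_fixture(which: str) -> tuple[IdentReport, ScanTable]:
    """Deterministic single-run fixtures for the two DIA window schemes.

    ``win80`` reproduces spectra complexity 2.27 and duplicate rate 1.58
    (utilization 1.44); ``win22`` reproduces 4.1 and 4.07 (utilization
    1.01).  The counts are the smallest integers realizing those ratios
    exactly; the precursor-to-scan geometry is constructed so the
    assignment reconstruction recovers them bit-for-bit.
    """
    if which not in _WORKED_EXAMPLES:
        raise ValueError(f"which must be one of {sorted(_WORKED_EXAMPLES)}")
    spec = _WORKED_EXAMPLES[which]
    return assignment_run(spec["n_windows"], spec["unique"], spec["identified"],
                          spec["redundant"], run_id=which)


def assignment_run(n_windows: int, n_unique: int, n_identified: int,
                   n_redundant: int, q_target: float = 0.75,
                   run_id: str = "assignment") -> tuple[IdentReport, ScanTable]:
    """Build a run whose assignment reconstruction yields exact target counts.

    Requires ``n_unique >= n_identified`` (DIA: at least as many precursors
    as identified multiplexed scans in this construction) and
    ``n_redundant >= n_unique``.  The decomposition of the returned run has
    exactly ``n_identified`` identified MS2 scans, ``n_redundant``
    redundant identifications and ``n_unique`` unique precursors.
    """
    if not (n_unique >= n_identified >= n_windows and n_redundant >= n_unique):
        raise ValueError("need n_unique >= n_identified >= n_windows and "
                         "n_redundant >= n_unique")
    n_win = n_windows
    which = run_id
    u_w = _split_total(n_identified, n_win)          # s_w first
    s_w = u_w.copy()
    u_w = s_w + _split_total(n_unique - n_identified, n_win)
    cap_w = u_w * s_w  # max redundant load a window can carry
    if n_redundant > int(cap_w.sum()):
        raise ValueError("n_redundant too large for this window geometry")
    # distribute the redundant load within [u_w, cap_w] per window, exactly
    r_w = np.clip(_split_total(n_redundant, n_win), u_w, cap_w)
    diff = int(n_redundant - r_w.sum())
    k = 0
    while diff != 0:
        if diff > 0 and r_w[k] < cap_w[k]:
            step = min(diff, int(cap_w[k] - r_w[k]))
            r_w[k] += step
            diff -= step
        elif diff < 0 and r_w[k] > u_w[k]:
            step = min(-diff, int(r_w[k] - u_w[k]))
            r_w[k] -= step
            diff += step
        k = (k + 1) % n_win

    mz_lo, mz_hi = 350.0, 350.0 + n_win * ((1200.0 - 350.0) / n_win)
    edges = np.linspace(mz_lo, mz_hi, n_win + 1)
    ct = (n_win + 1) * _MS2_DWELL_S / 60.0
    dwell = _MS2_DWELL_S / 60.0
    n_cycles = int(math.ceil(int(s_w.max()) / q_target))

    rows = []
    pidx = 0
    for w in range(n_win):
        off = (w + 1) * dwell
        for a, b in _window_intervals(int(u_w[w]), int(s_w[w]), int(r_w[w])):
            length = b - a
            apex = (a + (length - 1) / 2.0) * ct + off
            pw = (length - 0.5) * ct
            width = edges[w + 1] - edges[w]
            mz = edges[w] + width * (0.1 + 0.8 * ((pidx * 0.6180339887) % 1.0))
            seq = f"PEPTIDE{pidx:06d}K"
            rows.append((
                which, f"{seq}.2", seq, 2, mz, mz, apex, 0.0, pw / 1.7, pw,
                0, 1e6, 1e6, f"PROT{pidx // 5:05d}", 5e6, 0.001, length,
            ))
            pidx += 1
    report_df = pd.DataFrame(rows, columns=IDENT_COLUMNS)
    report = IdentReport(run_id=which, records=report_df,
                         gradient_length=n_cycles * ct)

    n_per_cycle = n_win + 1
    slot = np.tile(np.arange(n_per_cycle), n_cycles)
    cyc = np.repeat(np.arange(n_cycles), n_per_cycle)
    is_ms1 = slot == 0
    win = np.where(is_ms1, 0, slot - 1)
    scans = pd.DataFrame({
        "scan_index": np.arange(1, n_cycles * n_per_cycle + 1),
        "ms_level": np.where(is_ms1, 1, 2),
        "rt": cyc * ct + slot * dwell,
        "tic": np.where(is_ms1, 1e9, 2e7),
        "base_peak_intensity": np.where(is_ms1, 1e8, 2e6),
        "peak_count": np.where(is_ms1, 1500, 200),
        "injection_time": np.where(is_ms1, 5.0, 20.0),
        "iso_lo": np.where(is_ms1, np.nan, edges[win]),
        "iso_hi": np.where(is_ms1, np.nan, edges[win + 1]),
    })[SCAN_COLUMNS]
    return report, scan_table_from_frame(scans, which)
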