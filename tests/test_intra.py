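"""Per-run metrics and the DDA/DIA score decompositions."""

import numpy as np
import pandas as pd
import pytest

from cohortqc.intra import (
    DiaScoreDecomposition,
    compute_chromatography_metrics,
    compute_ident_metrics,
    compute_scan_metrics,
    compute_window_metrics,
    decompose_dda_score,
    decompose_dia_score,
    detect_ms1_features,
)
from cohortqc.report_io import IdentReport, scan_table_from_frame
from cohortqc.simulate import assignment_run, worked_example_fixture
from conftest import make_ident_frame, make_report, make_scan_frame, make_scan_table


def as_dict(metrics):
    return {m.metric_id: m for m in metrics}


class TestDiaDecomposition:
    @pytest.mark.parametrize("which,complexity,dup,util", [
        ("win80", 2.27, 1.58, 1.44),   # narrow-window operating point
        ("win22", 4.10, 4.07, 1.01),   # wide-window operating point
    ])
    def test_window_scheme_operating_points(self, which, complexity, dup, util):
        report, scans = worked_example_fixture(which)
        d = decompose_dia_score(report, scans)
        assert round(d.spectra_complexity, 2) == complexity
        assert round(d.dup_rate, 2) == dup
        assert round(d.utilization, 2) == util

    def test_synthetic_counts_recovered_exactly(self):
        report, scans = assignment_run(4, 1000, 800, 1600, q_target=0.8)
        d = decompose_dia_score(report, scans)
        assert (d.n_acquired_ms2, d.n_identified_ms2) == (1000, 800)
        assert (d.n_redundant_precursors, d.n_unique_precursors) == (1600, 1000)
        assert d.q_ms2 == 0.8
        assert (d.spectra_complexity, d.dup_rate, d.utilization) == (2.0, 1.6, 1.25)
        assert d.n_acquired_ms2 * d.q_ms2 * d.utilization == pytest.approx(1000)

    def test_one_precursor_per_scan_is_the_identity_case(self):
        # u == s == r: every identified scan yields exactly one precursor
        report, scans = assignment_run(4, 120, 120, 120)
        d = decompose_dia_score(report, scans)
        assert d.spectra_complexity == 1.0 and d.dup_rate == 1.0
        assert d.utilization == 1.0
        assert d.n_unique_precursors == d.n_identified_ms2 == 120

    def test_identity_holds_on_random_geometries(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            n_win = int(rng.integers(2, 8))
            s = int(rng.integers(2 * n_win, 200))
            u = s + int(rng.integers(0, 100))
            r = u + int(rng.integers(0, u))
            report, scans = assignment_run(n_win, u, s, r)
            d = decompose_dia_score(report, scans)
            assert d.n_identified_ms2 == s
            assert d.n_redundant_precursors == r
            lhs = d.n_acquired_ms2 * d.q_ms2 * d.utilization
            assert lhs == pytest.approx(d.n_unique_precursors, rel=1e-9)
            assert d.dup_rate >= 1.0
            assert d.utilization <= d.spectra_complexity + 1e-12

    def test_row_order_permutation_invariant(self):
        report, scans = assignment_run(3, 150, 120, 200)
        shuffled = IdentReport(
            run_id=report.run_id,
            records=report.records.sample(frac=1.0, random_state=5).reset_index(drop=True),
            gradient_length=report.gradient_length,
        )
        a = decompose_dia_score(report, scans)
        b = decompose_dia_score(shuffled, scans)
        assert a == b

    def test_requires_ms2_scans(self, toy_report):
        ms1_only = make_scan_frame(n_cycles=3, n_windows=1)
        ms1_only = ms1_only[ms1_only["ms_level"] == 1]
        with pytest.raises(ValueError):
            decompose_dia_score(toy_report, scan_table_from_frame(ms1_only, "x"))


class TestDdaDecomposition:
    def test_direct_counts(self):
        # 380 unique precursors, 20 identified twice -> 400 identified MS2
        df = make_ident_frame(380, n_ms2_matched=1)
        df.loc[:19, "n_ms2_matched"] = 2
        report = IdentReport(run_id="R00", records=df)
        scans = make_scan_table(n_cycles=100, n_windows=4)  # 400 MS2... need 500
        scans = make_scan_table(n_cycles=125, n_windows=4)  # 500 MS2 scans
        d = decompose_dda_score(report, scans)
        assert d.n_acquired_ms2 == 500 and d.n_identified_ms2 == 400
        assert d.q_ms2 == pytest.approx(0.8)
        assert d.p_ms2_per_precursor == pytest.approx(0.95)
        assert d.n_acquired_ms2 * d.q_ms2 * d.p_ms2_per_precursor == pytest.approx(380)

    def test_all_identified_uniquely(self):
        report = make_report(100, n_ms2_matched=1)
        scans = make_scan_table(n_cycles=25, n_windows=4)
        d = decompose_dda_score(report, scans)
        assert d.q_ms2 == 1.0 and d.p_ms2_per_precursor == 1.0

    def test_zero_identifications_marked_non_computable(self):
        report = make_report(0)
        scans = make_scan_table(n_cycles=5, n_windows=4)
        d = decompose_dda_score(report, scans)
        assert d.q_ms2 == 0.0 and not d.computable
        assert np.isnan(d.p_ms2_per_precursor)


class TestScanMetrics:
    def test_constant_tic_is_perfectly_stable(self):
        st = make_scan_table(n_cycles=50, n_windows=4, tic_ms1=1e9)
        m = as_dict(compute_scan_metrics(st))
        assert m["tic_cv"].value == 0.0
        assert m["tic_jump_count"].value == 0

    def test_cycle_time_from_construction(self):
        st = make_scan_table(n_cycles=20, n_windows=4, cycle_time_min=1.2 / 60.0)
        m = as_dict(compute_scan_metrics(st))
        assert m["median_cycle_time"].value == pytest.approx(1.2)

    def test_single_spike_counts_two_jumps(self):
        tic = np.full(100, 1e9)
        tic[40] = 1e11
        st = make_scan_table(n_cycles=100, n_windows=2, tic_ms1=tic)
        m = as_dict(compute_scan_metrics(st))
        assert m["tic_jump_count"].value == 2

    def test_scan_counts_and_fill_fraction(self):
        st = make_scan_table(n_cycles=10, n_windows=4,
                             injection_ms1=5.0, injection_ms2=20.0)
        m = as_dict(compute_scan_metrics(st))
        assert m["n_ms1_scans"].value == 10 and m["n_ms2_scans"].value == 40
        # all MS2 scans sit at the run max injection time
        assert m["fraction_scans_at_max_fill"].value == pytest.approx(40 / 50)

    def test_single_cycle_has_no_cycle_time(self):
        st = make_scan_table(n_cycles=1, n_windows=4)
        m = as_dict(compute_scan_metrics(st))
        assert not m["median_cycle_time"].computable


class TestIdentMetrics:
    def test_exact_masses_give_zero_ppm(self, toy_report):
        m = as_dict(compute_ident_metrics(toy_report))
        assert m["median_ms1_mass_accuracy"].value == 0.0

    def test_missed_cleavage_rate_counted(self):
        df = make_ident_frame(4, missed_cleavages=0)
        df.loc[2, "missed_cleavages"] = 1
        m = as_dict(compute_ident_metrics(IdentReport("R00", df)))
        assert m["missed_cleavage_rate"].value == pytest.approx(25.0)

    def test_dynamic_range_against_quantile_oracle(self):
        # sorted so that index 1 is exactly p1 and index 99 exactly p99
        n = 101
        prot_int = np.concatenate([[500.0], np.geomspace(1e3, 1e7, 99), [2e7]])
        df = make_ident_frame(n)
        df["protein_group"] = [f"P{i:04d}" for i in range(n)]
        df["protein_intensity"] = prot_int
        m = as_dict(compute_ident_metrics(IdentReport("R00", df)))
        p1, p99 = np.percentile(prot_int, [1, 99])
        assert m["intensity_dynamic_range"].value == pytest.approx(np.log10(p99 / p1))
        assert m["intensity_dynamic_range"].value == pytest.approx(4.0)

    def test_counts_hierarchy(self):
        rep = make_report(40)
        m = as_dict(compute_ident_metrics(rep))
        assert m["n_precursors"].value >= m["n_peptides"].value >= m["n_protein_groups"].value

    def test_sequence_coverage_needs_database(self):
        rep = make_report(8)
        m = as_dict(compute_ident_metrics(rep))
        assert not m["mean_protein_sequence_coverage"].computable
        db = {"PROT0000": "AAA" + "PEP00000K" + "CCC"}
        m2 = as_dict(compute_ident_metrics(rep, sequence_db=db))
        assert m2["mean_protein_sequence_coverage"].value == pytest.approx(
            100.0 * 9 / 15)

    def test_empty_report_all_non_computable(self):
        for m in compute_ident_metrics(make_report(0)):
            assert not m.computable and m.reason


class TestChromatographyMetrics:
    def test_uniform_elution_window(self):
        rng = np.random.default_rng(0)
        df = make_ident_frame(2000)
        df["apex_rt"] = rng.uniform(2.0, 28.0, 2000)
        rep = IdentReport("R00", df, gradient_length=30.0)
        m = as_dict(compute_chromatography_metrics(rep))
        assert m["lc_delay_time"].value == pytest.approx(2.0, abs=1.0)
        assert m["lc_tail_time"].value == pytest.approx(2.0, abs=1.0)
        assert 0.75 <= m["active_gradient_fraction"].value <= 0.95

    def test_late_start_bounds_delay(self):
        df = make_ident_frame(50)
        df["apex_rt"] = np.linspace(12.0, 28.0, 50)
        m = as_dict(compute_chromatography_metrics(IdentReport("R00", df, 30.0)))
        assert m["lc_delay_time"].value >= 12.0

    def test_empty_report_non_computable_with_reason(self):
        for m in compute_chromatography_metrics(make_report(0)):
            assert not m.computable and m.reason


class TestWindowMetrics:
    def test_mean_width_arithmetic(self, toy_report):
        st = make_scan_table(n_cycles=2, n_windows=22, mz_range=(350.0, 1200.0))
        m = as_dict(compute_window_metrics(st, toy_report))
        assert m["n_windows_per_cycle"].value == 22
        assert m["mean_window_width"].value == pytest.approx((1200 - 350) / 22)

    def test_uniform_precursors_are_balanced(self):
        st = make_scan_table(n_cycles=2, n_windows=80, mz_range=(350.0, 830.0))
        df = make_ident_frame(800)
        df["measured_mz"] = 350.0 + 480.0 * (np.arange(800) + 0.5) / 800.0
        m = as_dict(compute_window_metrics(st, IdentReport("R00", df)))
        assert m["window_load_imbalance"].value == pytest.approx(1.0)

    def test_containment_assignment(self):
        from cohortqc.intra import per_window_precursor_counts

        st = make_scan_table(n_cycles=1, n_windows=4, mz_range=(350.0, 374.0))
        df = make_ident_frame(1)
        df["measured_mz"] = 355.0  # first window is [350, 356)
        counts = per_window_precursor_counts(st, IdentReport("R00", df))
        assert list(counts["n_precursors"]) == [1, 0, 0, 0]


class TestFeatureDetection:
    def _with_centroids(self, traces, n_scans=7, rt_step=0.05):
        """traces: list of (mz, first_scan, length).  Returns a ScanTable."""
        st = make_scan_table(n_cycles=n_scans, n_windows=2,
                             cycle_time_min=rt_step)
        centroids = {}
        ms1_idx = list(st.ms1["scan_index"])
        for k, si in enumerate(ms1_idx):
            mzs = sorted(mz for mz, start, length in traces
                         if start <= k < start + length)
            if mzs:
                centroids[int(si)] = (np.array(mzs), np.full(len(mzs), 1e6))
        st.centroids = centroids
        return st

    def test_single_gaussian_trace_is_one_feature(self, toy_report):
        st = self._with_centroids([(500.0, 1, 5)])
        features, _ = detect_ms1_features(st, toy_report)
        assert len(features) == 1 and features[0].n_scans == 5

    def test_distant_traces_stay_separate(self, toy_report):
        st = self._with_centroids([(500.0, 0, 6), (500.0 * (1 + 50e-6), 0, 6)])
        features, _ = detect_ms1_features(st, toy_report, ppm_tol=10.0)
        assert len(features) == 2

    def test_matching_record_marks_identified(self):
        st = self._with_centroids([(500.0, 0, 6)])
        df = make_ident_frame(1)
        df["measured_mz"] = 500.000001
        df["apex_rt"] = 0.1
        features, frac = detect_ms1_features(st, IdentReport("R00", df))
        assert frac == 1.0 and features[0].identified

    def test_no_centroids_is_an_error(self, toy_report, toy_scans):
        with pytest.raises(ValueError):
            detect_ms1_features(toy_scans, toy_report)


class TestDecompositionTypes:
    def test_medians_lie_within_input_range(self, toy_report, toy_scans):
        for m in compute_scan_metrics(toy_scans) + compute_ident_metrics(toy_report):
            if m.computable and m.metric_id.startswith("median_cycle"):
                diffs = np.diff(toy_scans.ms1["rt"].to_numpy()) * 60
                assert diffs.min() <= m.value <= diffs.max()

    def test_fraction_metrics_bounded(self, toy_scans):
        m = as_dict(compute_scan_metrics(toy_scans))
        assert 0.0 <= m["fraction_scans_at_max_fill"].value <= 1.0
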