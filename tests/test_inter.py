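"""Cohort-level metrics: contaminant fractions, RT MSE, distribution stats,
2-SD scoring and the low-quality rule."""

import numpy as np
import pandas as pd
import pytest

from cohortqc.inter import (
    ContaminantPanel,
    InterConfig,
    _score_row,
    build_cohort_matrix,
    contaminant_fraction,
    flag_low_quality,
    load_panels,
    quant_distribution_metrics,
    robust_sd,
    rt_deviation_metrics,
)
from cohortqc.registry import inter_metric_ids
from cohortqc.report_io import IdentReport
from cohortqc.simulate import Anomaly, CohortConfig, generate_cohort
from conftest import make_ident_frame, make_report

PANEL = ContaminantPanel("toy", frozenset({"ALB", "HBB"}))


def reports_from_frames(frames):
    return [IdentReport(run_id=str(df["run_id"].iloc[0]), records=df) for df in frames]


class TestContaminantFraction:
    def test_absent_panel_is_zero(self):
        assert contaminant_fraction(make_report(20), PANEL) == 0.0

    def test_all_in_panel_is_one(self):
        rep = make_report(10, protein_group="ALB")
        assert contaminant_fraction(rep, PANEL) == 1.0

    def test_two_protein_arithmetic(self):
        df = make_ident_frame(2)
        df["protein_group"] = ["ALB", "PROT1"]
        df["protein_intensity"] = [300.0, 700.0]
        assert contaminant_fraction(IdentReport("R00", df), PANEL) == pytest.approx(0.30)

    def test_group_member_matching_is_case_insensitive(self):
        df = make_ident_frame(2)
        df["protein_group"] = ["sp|x; alb ", "PROT1"]
        df["protein_intensity"] = [250.0, 750.0]
        assert contaminant_fraction(IdentReport("R00", df), PANEL) == pytest.approx(0.25)

    def test_zero_total_intensity_non_computable(self):
        rep = make_report(5, protein_intensity=0.0)
        assert np.isnan(contaminant_fraction(rep, PANEL))

    def test_default_panels_load_and_normalize(self):
        panels = load_panels()
        assert set(panels) == {"erythrocyte", "cellular_debris", "serum_high_abundance"}
        assert all(m == m.upper() for p in panels.values() for m in p.members)


class TestRtDeviation:
    def test_identical_runs_have_zero_mse(self):
        reps = [make_report(60, run_id=f"R{i}", seed=0) for i in range(3)]
        for i, r in enumerate(reps):
            r.records["run_id"] = f"R{i}"
        _, mse = rt_deviation_metrics(reps, min_shared=10)
        off = mse.values[~np.eye(3, dtype=bool)]
        assert np.allclose(off, 0.0)

    def test_constant_shift_closed_form(self):
        a = make_ident_frame(100)
        b = a.copy()
        b["run_id"] = "R01"
        b["apex_rt"] = b["apex_rt"] + 0.5
        _, mse = rt_deviation_metrics(reports_from_frames([a, b]), min_shared=10)
        assert mse.loc["R00", "R01"] == pytest.approx(0.25)

    def test_symmetric_with_zero_diagonal(self):
        frames = []
        rng = np.random.default_rng(7)
        for i in range(4):
            df = make_ident_frame(80, run_id=f"R{i}")
            df["apex_rt"] = df["apex_rt"] + rng.normal(0, 0.1, len(df))
            frames.append(df)
        _, mse = rt_deviation_metrics(reports_from_frames(frames), min_shared=10)
        assert np.allclose(mse.values, mse.values.T)
        assert np.allclose(np.diag(mse.values), 0.0)

    def test_insufficient_overlap_is_non_computable(self):
        a = make_ident_frame(30, run_id="R00")
        b = make_ident_frame(30, run_id="R01")
        b["precursor_id"] = [f"OTHER{i}.2" for i in range(30)]
        _, mse = rt_deviation_metrics(reports_from_frames([a, b]), min_shared=10)
        assert np.isnan(mse.loc["R00", "R01"])

    def test_median_abs_delta_rt_per_run(self):
        a = make_ident_frame(50, delta_rt=0.2)
        b = make_ident_frame(50, run_id="R01", delta_rt=-0.1)
        lc1, _ = rt_deviation_metrics(reports_from_frames([a, b]), min_shared=10)
        assert lc1["R00"] == pytest.approx(0.2)
        assert lc1["R01"] == pytest.approx(0.1)


class TestQuantDistribution:
    def test_identical_runs_perfectly_correlated(self):
        frames = [make_ident_frame(80, run_id=f"R{i}", seed=1) for i in range(2)]
        for i, df in enumerate(frames):
            df["run_id"] = f"R{i}"
        out = quant_distribution_metrics(reports_from_frames(frames), "precursor",
                                         min_shared=10)
        assert np.allclose(out["median_pearson"], 1.0)
        assert np.allclose(out["norm_factor_log2"], 0.0)

    def test_median_and_iqr_quantile_oracle(self):
        df = make_ident_frame(5)
        df["precursor_intensity"] = 2.0 ** np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        other = make_ident_frame(5, run_id="R01")
        out = quant_distribution_metrics(
            reports_from_frames([df, other]), "precursor", min_shared=5)
        assert out.loc["R00", "median_log2"] == pytest.approx(3.0)
        assert out.loc["R00", "iqr_log2"] == pytest.approx(2.0)
        assert out.loc["R00", "count"] == 5

    def test_robust_sd_mad_oracle_vector(self):
        assert robust_sd([1.0, 1.0, 1.0, 9.0]) == 0.0

    def test_robust_sd_against_independent_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            x = rng.normal(size=rng.integers(3, 40)) * rng.uniform(0.1, 50)
            med = sorted(x)[len(x) // 2] if len(x) % 2 else np.median(x)
            oracle = 1.4826 * np.median(np.abs(np.asarray(x) - np.median(x)))
            assert robust_sd(x) == pytest.approx(oracle, rel=1e-12)

    def test_levels_produce_six_stats(self, toy_report):
        other = make_report(40, run_id="R01", seed=2)
        for level in ("precursor", "peptide", "protein"):
            out = quant_distribution_metrics([toy_report, other], level, min_shared=5)
            assert list(out.columns) == ["count", "median_log2", "iqr_log2",
                                         "robust_sd_log2", "median_pearson",
                                         "norm_factor_log2"]


@pytest.fixture(scope="module")
def clean_cohort():
    data = generate_cohort(CohortConfig(n_runs=8, seed=123, with_scans=False))
    return build_cohort_matrix(data.reports)


class TestCohortMatrix:
    def test_exactly_23_metrics(self, clean_cohort):
        assert list(clean_cohort.values.index) == inter_metric_ids()
        assert len(clean_cohort.values.index) == 23
        assert clean_cohort.values.notna().all().all()

    def test_scores_bounded(self, clean_cohort):
        s = clean_cohort.scores.to_numpy()
        assert np.nanmin(s) >= 1.0 and np.nanmax(s) <= 5.0

    def test_contaminant_fractions_bounded(self, clean_cohort):
        sp = clean_cohort.values.loc[["SP1", "SP2", "SP3"]].to_numpy()
        assert (sp >= 0).all() and (sp <= 1).all()

    def test_pairwise_matrices_symmetric(self, clean_cohort):
        mse = clean_cohort.pairwise["rt_mse"]
        assert np.allclose(mse.values, mse.values.T)
        assert np.allclose(np.diag(mse.values), 0.0)
        pear = clean_cohort.pairwise["pearson_log2_protein"]
        assert np.allclose(np.diag(pear.values), 1.0)

    def test_planted_extreme_contaminant_is_flagged(self):
        data = generate_cohort(CohortConfig(
            n_runs=10, seed=5, with_scans=False,
            anomalies=[Anomaly(3, "contamination", 0.5)]))
        matrix = build_cohort_matrix(data.reports)
        assert bool(matrix.flags.loc["SP1", "R03"])
        assert matrix.scores.loc["SP1", "R03"] == 1.0

    def test_two_run_cohort_reports_values_only(self):
        data = generate_cohort(CohortConfig(n_runs=2, seed=9, with_scans=False))
        matrix = build_cohort_matrix(data.reports)
        assert not matrix.scored
        assert matrix.values.notna().any().any()
        assert not matrix.flags.any().any()


class TestScoreRow:
    def test_flags_invariant_under_affine_rescaling(self):
        rng = np.random.default_rng(3)
        v = rng.normal(10, 2, 20)
        v[4] += 20.0
        for direction in ("bad_high", "bad_low"):
            s0, f0 = _score_row(v, direction, 2.0)
            s1, f1 = _score_row(3.5 * v + 11.0, direction, 2.0)
            assert (f0 == f1).all()
            np.testing.assert_allclose(s0, s1, atol=1e-9)

    def test_bad_abs_flags_both_signs(self):
        v = np.concatenate([np.random.default_rng(0).uniform(-0.05, 0.05, 18),
                            [1.5, -1.4]])
        _, f = _score_row(v, "bad_abs", 2.0)
        assert f[18] and f[19]

    def test_good_side_scores_five(self):
        v = np.array([1.0, 2.0, 3.0, 4.0, 10.0])
        s, _ = _score_row(v, "bad_high", 2.0)
        assert s[0] == 5.0 and s[1] == 5.0  # at/below median

    def test_constant_metric_scores_five_no_flags(self):
        s, f = _score_row(np.full(10, 3.3), "bad_high", 2.0)
        assert (s == 5.0).all() and not f.any()


class TestFlagLowQuality:
    def _matrix_with_counts(self, counts):
        runs = [f"R{i:02d}" for i in range(len(counts))]
        mids = inter_metric_ids()
        flags = pd.DataFrame(False, index=mids, columns=runs)
        for run, c in zip(runs, counts):
            flags.loc[mids[:c], run] = True
        from cohortqc.inter import CohortMetricMatrix

        zeros = pd.DataFrame(0.0, index=mids, columns=runs)
        return CohortMetricMatrix(runs=runs, values=zeros, scores=zeros, flags=flags)

    def test_threshold_boundary(self):
        m = self._matrix_with_counts([7, 6, 0, 23])
        assert flag_low_quality(m, 7) == {"R00", "R03"}

    def test_clean_cohort_empty(self):
        assert flag_low_quality(self._matrix_with_counts([0, 1, 2])) == set()
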