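"""Grid evaluation, window intersection, pooling, reports and the CLI."""

import math

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from vancauc import gridsearch as gs
from vancauc import nca
from vancauc import simcohort as sc
from vancauc import sparse_auc as sp
from vancauc.agreement import AgreementSummary
from vancauc.cli import main as cli_main

CFG = gs.EvaluationConfig()


def _refs(profiles):
    return gs.reference_nca(profiles, CFG)


def _dummy_summary(pct):
    return AgreementSummary(
        n=10, grand_mean=100.0, mean_diff=pct, pct_mean_diff=pct, sd_diff=1.0,
        loa_low=pct - 1.96, loa_high=pct + 1.96, pearson_r=0.99, pearson_p=0.0,
        lin_ccc=0.98, lin_p=0.0, ols_slope=1.0, ols_intercept=0.0, ols_r2=0.98,
    )


def _dummy_cell(cohort, model, t1, t2, acceptable, pct=1.0):
    rng = np.random.default_rng(int(t1 + t2))
    ref = rng.uniform(50, 150, 10)
    data = pd.DataFrame(
        {"subject_id": [f"s{i}" for i in range(10)], "ref_auc": ref,
         "est_auc": ref * (1 + pct / 100), "ke": 0.2, "cl": 1.0, "vd": 5.0,
         "t_half": 3.0}
    )
    return gs.GridCell(cohort, model, t1, t2, 10, 0,
                       _dummy_summary(pct if acceptable else 8.0), acceptable, data)


class TestEvaluateCell:
    def test_injected_identity_gives_zero_bias(self, noise_free_pediatric_cohort):
        _, profiles, _ = noise_free_pediatric_cohort
        fake_refs = {}
        for p in profiles:
            est = sp.estimate(sp.two_point_from_profile(p, 60, 300), "model2")
            fake_refs[p.subject_id] = nca.NcaResult(
                p.subject_id, est.auc_f, est.auc_f, est.ke, 3,
                p.regimen.dose_mg / est.auc_f, 1.0, math.log(2) / est.ke,
            )
        cell = gs.evaluate_cell(profiles, fake_refs, "model2", 60, 300, 5.0, "pediatric")
        assert cell.summary.pct_mean_diff == pytest.approx(0.0, abs=1e-12)
        assert cell.acceptable

    def test_unknown_time_pair_is_error(self, noise_free_pediatric_cohort):
        _, profiles, _ = noise_free_pediatric_cohort
        with pytest.raises(KeyError):
            gs.evaluate_cell(profiles, _refs(profiles), "model2", 45, 300)

    def test_acceptability_is_strict_inequality(self):
        assert not gs._is_acceptable(-5.0, 5.0)
        assert not gs._is_acceptable(5.0, 5.0)
        assert gs._is_acceptable(4.999, 5.0)

    def test_noise_free_model1_biased_below_model2(self, noise_free_pediatric_cohort):
        _, profiles, _ = noise_free_pediatric_cohort
        refs = _refs(profiles)
        for t1, t2 in ((0, 240), (60, 240), (120, 300)):
            m1 = gs.evaluate_cell(profiles, refs, "model1", t1, t2, 5.0)
            m2 = gs.evaluate_cell(profiles, refs, "model2", t1, t2, 5.0)
            assert m1.summary.pct_mean_diff < m2.summary.pct_mean_diff

    def test_two_point_ke_converges_to_lambda_z(self, noise_free_pediatric_cohort):
        # later C1 samples sit deeper in the beta phase
        _, profiles, _ = noise_free_pediatric_cohort
        p = profiles[0]
        lz = nca.lambda_z(p, 3)
        gaps = [
            abs(sp.estimate(sp.two_point_from_profile(p, t1, 300), "model2").ke - lz)
            for t1 in (30, 60, 120)
        ]
        assert gaps[0] > gaps[1] > gaps[2]


class TestRunGrid:
    def test_cell_counts_per_cohort(self, noise_free_adult_cohort, noise_free_pediatric_cohort):
        _, adult, _ = noise_free_adult_cohort
        _, ped, _ = noise_free_pediatric_cohort
        cells = gs.run_grid({"adult": adult, "pediatric": ped})
        n_adult = sum(c.cohort == "adult" for c in cells)
        n_ped = sum(c.cohort == "pediatric" for c in cells)
        # adult: 7 C1 x {240} x 2 models; pediatric: (6 + 7) pairs x 2 models
        assert n_adult == 14
        assert n_ped == 26

    def test_empty_model_list_gives_empty_grid(self, noise_free_adult_cohort):
        _, adult, _ = noise_free_adult_cohort
        cfg = gs.EvaluationConfig(models=())
        assert gs.run_grid({"adult": adult}, cfg) == []

    def test_rerun_equality(self, noise_free_adult_cohort):
        _, adult, _ = noise_free_adult_cohort
        a = gs.run_grid({"adult": adult})
        b = gs.run_grid({"adult": adult})
        assert [c.summary.pct_mean_diff for c in a] == [c.summary.pct_mean_diff for c in b]

    def test_unknown_cohort_is_error(self, noise_free_adult_cohort):
        _, adult, _ = noise_free_adult_cohort
        with pytest.raises(KeyError):
            gs.run_grid({"elderly": adult})


class TestSelectAndIntersect:
    def test_reported_window_pattern(self):
        """The adult/pediatric acceptability pattern of the source analysis
        must intersect to model2, C1 60-90 min, C2 240-300 min."""
        cells = []
        for t1 in (0, 10, 20, 40, 60, 90, 120):
            cells.append(_dummy_cell("adult", "model1", t1, 240, acceptable=False))
            cells.append(_dummy_cell("adult", "model2", t1, 240, t1 in (60, 90)))
        ped_ok_m1 = {(0, 240), (0, 300), (15, 300)}
        ped_ok_m2 = {(30, 240), (60, 240), (120, 240), (180, 240),
                     (60, 300), (120, 300), (180, 300)}
        for t2 in (240, 300):
            for t1 in (0, 15, 30, 60, 120, 180, 240):
                if t1 >= t2:
                    continue
                cells.append(_dummy_cell("pediatric", "model1", t1, t2, (t1, t2) in ped_ok_m1))
                cells.append(_dummy_cell("pediatric", "model2", t1, t2, (t1, t2) in ped_ok_m2))
        sel = gs.select_and_intersect(cells)
        assert len(sel.intersections) == 1
        w = sel.intersections[0]
        assert w.model == "model2"
        assert w.t1_window == (60, 90)
        assert w.t2_window == (240, 300)
        assert {(c.cohort, c.t1_min, c.t2_min) for c in w.cells} == {
            ("adult", 60, 240), ("adult", 90, 240),
            ("pediatric", 60, 240), ("pediatric", 60, 300),
        }

    def test_empty_when_one_cohort_has_no_acceptable_cells(self):
        cells = [
            _dummy_cell("adult", "model2", 60, 240, acceptable=False),
            _dummy_cell("pediatric", "model2", 60, 240, acceptable=True),
        ]
        sel = gs.select_and_intersect(cells)
        assert sel.intersections == ()
        assert len(sel.acceptable) == 1

    def test_single_shared_cell_gives_point_window(self):
        cells = [
            _dummy_cell("adult", "model2", 60, 240, acceptable=True),
            _dummy_cell("adult", "model2", 90, 240, acceptable=False),
            _dummy_cell("pediatric", "model2", 60, 240, acceptable=True),
            _dummy_cell("pediatric", "model2", 60, 300, acceptable=False),
        ]
        sel = gs.select_and_intersect(cells)
        assert len(sel.intersections) == 1
        assert sel.intersections[0].t1_window == (60, 60)
        assert sel.intersections[0].t2_window == (240, 240)


class TestPooledRegression:
    def test_identity_pool(self):
        c = _dummy_cell("adult", "model2", 60, 240, True, pct=0.0)
        slope, intercept, r = gs.pooled_regression([c])
        assert slope == pytest.approx(1.0)
        assert intercept == pytest.approx(0.0, abs=1e-9)
        assert r == pytest.approx(1.0)

    def test_pool_of_one_cell_equals_cell_fit(self):
        c = _dummy_cell("adult", "model2", 60, 240, True, pct=3.0)
        from vancauc.agreement import ols_fit

        slope, intercept, _ = gs.pooled_regression([c])
        s2, i2, _ = ols_fit(c.data["ref_auc"], c.data["est_auc"])
        assert (slope, intercept) == (pytest.approx(s2), pytest.approx(i2))

    def test_recovers_synthetic_line_across_cells(self):
        rng = np.random.default_rng(9)
        cells = []
        for cohort, lo, hi in (("adult", 200, 700), ("pediatric", 40, 200)):
            ref = rng.uniform(lo, hi, 40)
            est = 0.15 + 1.03 * ref + rng.normal(0, 1.0, 40)
            data = pd.DataFrame(
                {"subject_id": range(40), "ref_auc": ref, "est_auc": est,
                 "ke": 0.2, "cl": 1.0, "vd": 5.0, "t_half": 3.0}
            )
            cells.append(gs.GridCell(cohort, "model2", 60, 240, 40, 0,
                                     _dummy_summary(1.0), True, data))
        slope, intercept, r = gs.pooled_regression(cells)
        assert slope == pytest.approx(1.03, abs=0.01)
        assert intercept == pytest.approx(0.15, abs=2.0)
        assert r > 0.99

    def test_empty_pool_is_error(self):
        with pytest.raises(ValueError):
            gs.pooled_regression([])


class TestReport:
    def test_writes_all_files(self, noise_free_adult_cohort, noise_free_pediatric_cohort, tmp_path):
        _, adult, _ = noise_free_adult_cohort
        _, ped, _ = noise_free_pediatric_cohort
        cohorts = {"adult": adult, "pediatric": ped}
        cells = gs.run_grid(cohorts)
        sel = gs.select_and_intersect(cells)
        nca_by = {k: gs.reference_nca(v, CFG) for k, v in cohorts.items()}
        paths = gs.report(cells, sel, tmp_path, nca_by)
        grid = pd.read_csv(paths["grid"])
        assert len(grid) == 40
        assert {"mean", "pct_mean_diff", "loa_low", "lin_ccc", "acceptable"} <= set(grid.columns)
        assert paths["pk_summary"].exists() and paths["pooled"].exists()
        pk = pd.read_csv(paths["pk_summary"])
        assert set(pk["source"]) >= {"reference"}

    def test_empty_selection_writes_header_only(self, tmp_path):
        cells = [_dummy_cell("adult", "model2", 60, 240, False)]
        sel = gs.select_and_intersect(cells)
        paths = gs.report(cells, sel, tmp_path)
        selected = pd.read_csv(paths["selected"])
        assert len(selected) == 0
        assert "pct_mean_diff" in selected.columns


class TestCli:
    def test_simulate_then_evaluate_end_to_end(self, tmp_path):
        runner = CliRunner()
        res = runner.invoke(
            cli_main,
            ["simulate", "--cohort", "both", "--n", "8", "--seed", "3",
             "--out", str(tmp_path)],
        )
        assert res.exit_code == 0, res.output
        assert (tmp_path / "profiles.csv").exists()
        truth = pd.read_csv(tmp_path / "truth.csv")
        assert len(truth) == 16
        res = runner.invoke(
            cli_main,
            ["evaluate", "--profiles", str(tmp_path / "profiles.csv"),
             "--out", str(tmp_path / "eval")],
        )
        assert res.exit_code == 0, res.output
        assert (tmp_path / "eval" / "grid.csv").exists()
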