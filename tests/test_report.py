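"""Pipeline orchestration, report bundle, baseline comparisons, and the CLI."""

import json
from dataclasses import replace

import numpy as np
import pytest
from click.testing import CliRunner

from ptpvalid.cli import main as cli_main
from ptpvalid.cohort import CohortTable, read_cohort
from ptpvalid.models import example_confirm_style_spec, example_gem_style_spec
from ptpvalid.report import (
    RunConfig,
    baseline_table,
    render_text_report,
    run_validation,
    validate_cohort,
)
from ptpvalid.synthetic import default_configs, generate_cohort

from conftest import make_record

TOY_CSV = """id,age,sex,chest_pain,diabetes,hypertension,hyperlipidemia,smoking,family_history,ccs,obstructive_cad
r1,55,female,nonanginal,0,0,0,0,0,0,0
r2,55,male,nonanginal,0,0,0,0,0,0,0
r3,55,male,typical,0,0,0,0,0,0,1
r4,55,female,typical,0,0,0,0,0,0,1
r5,55,male,nonanginal,0,0,0,0,0,0,1
"""

OLD_MODEL = {
    "name": "sex-only",
    "intercept": -2.2,
    "terms": [{"covariate": "sex_male", "coefficient": 2.0}],
}
NEW_MODEL = {
    "name": "pain-only",
    "intercept": -2.2,
    "terms": [{"covariate": "chest_pain_typical", "coefficient": 4.0}],
}


@pytest.fixture
def toy_run(tmp_path):
    (tmp_path / "cohort.csv").write_text(TOY_CSV)
    (tmp_path / "old.json").write_text(json.dumps(OLD_MODEL))
    (tmp_path / "new.json").write_text(json.dumps(NEW_MODEL))
    return tmp_path


class TestValidateCohort:
    def test_toy_cohort_by_hand(self, toy_run):
        """Five records whose PTPs and categories were computed by hand:
        old model gives females 0.0997 (low), males 0.45 (medium); new model
        gives nonanginal 0.0997 (low), typical 0.858 (high)."""
        cohort = read_cohort(toy_run / "cohort.csv", stratum_label="toy")
        from ptpvalid.models import load_model_spec

        rep = validate_cohort(
            cohort,
            load_model_spec(toy_run / "old.json"),
            load_model_spec(toy_run / "new.json"),
        )
        neg = np.array(rep["reclassification"]["counts_neg"])
        pos = np.array(rep["reclassification"]["counts_pos"])
        assert neg[0, 0] == 1 and neg[0, 1] == 1 and neg.sum() == 2
        assert pos[2, 1] == 1 and pos[2, 0] == 1 and pos[0, 1] == 1 and pos.sum() == 3
        r = rep["reclassification"]["nri"]
        assert r["nri_pos"] == pytest.approx(1 / 3)
        assert r["nri_neg"] == pytest.approx(1 / 2)
        assert rep["strategy"]["n_old_medium_neg"] == 1
        assert rep["strategy"]["n_moved_to_low_neg"] == 1

    def test_self_comparison_is_all_null(self):
        cfg0, _ = default_configs(seed=21)
        cohort = generate_cohort(replace(cfg0, n=600))
        m = example_gem_style_spec()
        rep = validate_cohort(cohort, m, m)
        assert rep["discrimination"]["delong"]["diff"] == 0.0
        assert rep["discrimination"]["idi"]["idi"] == 0.0
        assert rep["reclassification"]["nri"]["nri_overall"] == 0.0
        assert rep["strategy"]["n_moved_to_low_neg"] == 0

    def test_report_sections_present_and_text_renders(self):
        cfg0, _ = default_configs(seed=22)
        cohort = generate_cohort(replace(cfg0, n=800))
        rep = validate_cohort(
            cohort, example_confirm_style_spec(), example_gem_style_spec()
        )
        for key in ("discrimination", "reclassification", "calibration", "strategy", "mace"):
            assert key in rep
        assert rep["mace"]["n_followed"] + rep["mace"]["n_excluded_no_followup"] == 800
        text = render_text_report(rep)
        assert "AUC" in text and "NRI" in text and "H-L" in text
        json.dumps(rep)  # machine-readable without loss


class TestRunValidation:
    def test_bundle_written(self, toy_run):
        rc = RunConfig(
            cohort_paths=(str(toy_run / "cohort.csv"),),
            model_old_path=str(toy_run / "old.json"),
            model_new_path=str(toy_run / "new.json"),
            out_dir=str(toy_run / "out"),
        )
        reports = run_validation(rc)
        assert len(reports) == 1
        out = toy_run / "out"
        assert json.loads((out / "report.json").read_text())[0]["n"] == 5
        assert (out / "reclassification.csv").exists()
        assert (out / "report.txt").read_text().startswith("Stratum")
        assert "seed=0" in (out / "run.log").read_text()

    def test_invalid_cutoffs_rejected(self):
        with pytest.raises(ValueError):
            RunConfig(
                cohort_paths=("x.csv",),
                model_old_path="o",
                model_new_path="n",
                cutoffs=(0.85, 0.15),
            )


class TestBaselineTable:
    def _cohort(self, n_pos, n_neg, **overrides):
        records = []
        for i in range(n_pos + n_neg):
            y = i < n_pos
            kw = dict(id=f"b{i}", obstructive_cad=y)
            for key, (pos_val, neg_val) in overrides.items():
                kw[key] = pos_val if y else neg_val
            records.append(make_record(**kw))
        return CohortTable(records)

    def test_identical_binary_variable_gives_fisher_p_one(self):
        cohort = self._cohort(10, 10, smoking=(True, True))
        rows = {r.variable: r for r in baseline_table(cohort)}
        assert rows["smoking"].test == "untestable"  # all one level
        # 50/50 in both groups: a genuinely identical 2x2 distribution
        records = cohort.records
        for i, r in enumerate(records):
            r.smoking = i % 2 == 0
        rows = {r.variable: r for r in baseline_table(CohortTable(records))}
        assert rows["smoking"].p_value == pytest.approx(1.0)

    def test_perfectly_separated_two_by_two_is_significant(self):
        cohort = self._cohort(10, 10, diabetes=(True, False))
        rows = {r.variable: r for r in baseline_table(cohort)}
        assert rows["diabetes"].test in ("fisher", "chi_square")
        assert rows["diabetes"].p_value < 0.001

    def test_equal_continuous_samples_give_zero_t(self):
        cohort = self._cohort(10, 10)
        ages = np.linspace(40, 70, 10)
        for i, r in enumerate(cohort.records):
            r.age = float(ages[i % 10])
        rows = {r.variable: r for r in baseline_table(CohortTable(cohort.records))}
        assert rows["age"].test == "t"
        assert rows["age"].statistic == pytest.approx(0.0, abs=1e-12)

    def test_sparse_two_by_two_uses_fisher(self):
        cohort = self._cohort(6, 6, family_history=(True, False))
        # 6/0 vs 0/6 with expected cells of 3 -> Fisher
        rows = {r.variable: r for r in baseline_table(cohort)}
        assert rows["family_history"].test == "fisher"


class TestCli:
    def test_generate_and_validate_round_trip(self, tmp_path):
        runner = CliRunner()
        res = runner.invoke(
            cli_main,
            ["generate", "--stratum", "0rf", "--n", "400", "--seed", "5",
             "--out", str(tmp_path / "gen")],
        )
        assert res.exit_code == 0, res.output
        from importlib import resources

        old_cfg = tmp_path / "old.json"
        new_cfg = tmp_path / "new.json"
        old_cfg.write_text(
            resources.files("ptpvalid.data").joinpath("confirm_style_example.json").read_text()
        )
        new_cfg.write_text(
            resources.files("ptpvalid.data").joinpath("gem_style_example.json").read_text()
        )
        res = runner.invoke(
            cli_main,
            [
                "validate",
                "--cohort", str(tmp_path / "gen" / "cohort_0rf.csv"),
                "--events", str(tmp_path / "gen" / "events_0rf.csv"),
                "--model-old", str(old_cfg),
                "--model-new", str(new_cfg),
                "--out", str(tmp_path / "rep"),
            ],
        )
        assert res.exit_code == 0, res.output
        assert "NRI overall" in res.output
        assert (tmp_path / "rep" / "report.json").exists()

    def test_compare_tables_prints_published_statistics(self):
        runner = CliRunner()
        res = runner.invoke(cli_main, ["compare-tables", "--stratum", "0 RF"])
        assert res.exit_code == 0, res.output
        out = json.loads(res.output)
        assert out["up_neg"] == 72 and out["down_neg"] == 269
        assert out["nri_neg_pct"] == 23.51
        assert out["idi_pct"] == 5.0
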