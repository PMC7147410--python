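import numpy as np
import pandas as pd
import pytest
import yaml
from click.testing import CliRunner

from cumfp.cli import main
from cumfp.reporting import (
    RunConfig,
    build_cohort_inputs,
    compare_scenarios,
    run_reproduction,
    scenario_table,
    write_table_csv,
    zorzi_check,
)
from cumfp.schedules import make_gompertz_mortality, write_schedule_csv
from cumfp.survivorship import linear_survivorship


class TestRunConfig:
    def test_default_config_calibrates(self):
        cfg = RunConfig.default()
        inputs = build_cohort_inputs(cfg)
        assert inputs.curve.at(74) / inputs.curve.at(50) == pytest.approx(0.54)
        assert inputs.prevalence_at_start == pytest.approx(1 - inputs.curve.f50)

    def test_requires_exactly_one_input_block(self):
        with pytest.raises(ValueError, match="exactly one"):
            RunConfig()
        with pytest.raises(ValueError, match="exactly one"):
            RunConfig(calibration={}, schedules={})

    def test_yaml_round_trip(self, tmp_path):
        path = tmp_path / "run.yaml"
        path.write_text(
            yaml.safe_dump(
                {
                    "calibration": {
                        "ratio_74": 0.54,
                        "anchor_scenario": "i2_sp98",
                        "anchor_value": 15102,
                    },
                    "scenarios": ["i1_sp98", "i2_sp98"],
                    "out_dir": str(tmp_path / "out"),
                }
            )
        )
        cfg = RunConfig.from_yaml(path)
        assert [sc.label for sc in cfg.selected_scenarios()] == ["i1_sp98", "i2_sp98"]

    def test_unknown_keys_and_labels_rejected(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text("calibration: {ratio_74: 0.54, anchor_scenario: i2_sp98, anchor_value: 15102}\nbogus: 1\n")
        with pytest.raises(ValueError, match="bogus"):
            RunConfig.from_yaml(path)
        cfg = RunConfig(
            calibration={"ratio_74": 0.54, "anchor_scenario": "i2_sp98",
                         "anchor_value": 15102},
            scenarios=["no_such_label"],
        )
        with pytest.raises(KeyError, match="no_such_label"):
            cfg.selected_scenarios()

    def test_explicit_schedule_files_drive_the_cohort(self, tmp_path):
        mort = make_gompertz_mortality(2e-5, 0.085, range(50, 75))
        inc = make_gompertz_mortality(3e-4, 0.05, range(50, 75))  # any valid schedule
        write_schedule_csv(mort, tmp_path / "mort.csv")
        write_schedule_csv(inc, tmp_path / "inc.csv")
        cfg = RunConfig(
            schedules={
                "mortality": str(tmp_path / "mort.csv"),
                "incidence": str(tmp_path / "inc.csv"),
                "prevalence_at_start": 0.2,
            }
        )
        inputs = build_cohort_inputs(cfg)
        assert inputs.curve.f50 == pytest.approx(0.8)
        table = scenario_table(inputs, cfg.selected_scenarios()[:2])
        assert table.shape == (25, 2)


class TestReproductionTables:
    def test_anchor_cell_is_reproduced_exactly(self, reproduction_tables):
        assert reproduction_tables["base"]["i2_sp98"].loc[74] == pytest.approx(
            15_102.0, abs=1e-6
        )

    def test_columns_monotone_and_sensitivity_below_base(self, reproduction_tables):
        base, sens = reproduction_tables["base"], reproduction_tables["sensitivity"]
        assert base.shape == (25, 11)
        for col in base.columns:
            assert base[col].is_monotonic_increasing
            assert np.all(sens[col] <= base[col] + 1e-9)

    def test_free50_table_is_base_divided_by_f50(
        self, reproduction_tables, calibrated_f50
    ):
        np.testing.assert_allclose(
            reproduction_tables["free50"].values,
            reproduction_tables["base"].values / calibrated_f50,
            rtol=1e-12,
        )

    def test_rounded_csv_round_trips(self, reproduction_tables, tmp_path):
        path = tmp_path / "table.csv"
        write_table_csv(reproduction_tables["base"], path)
        back = pd.read_csv(path, index_col="age")
        assert back.shape == (25, 11)
        assert (back.dtypes == int).all()
        np.testing.assert_array_equal(
            back.values, np.floor(reproduction_tables["base"].values + 0.5)
        )

    def test_comparisons_are_pairwise_percent_differences(self, reproduction_tables):
        base = reproduction_tables["base"]
        same = compare_scenarios(base, [("i2_sp98", "i2_sp98")])
        assert same["pct_difference"].iloc[0] == 0.0
        cmp = compare_scenarios(base, [("i1_sp98", "i2_sp98")])
        expected = 100 * (base["i1_sp98"].loc[74] / base["i2_sp98"].loc[74] - 1)
        assert cmp["pct_difference"].iloc[0] == pytest.approx(expected)

    def test_run_writes_all_csvs(self, tmp_path):
        cfg = RunConfig(
            calibration={"ratio_74": 0.54, "anchor_scenario": "i2_sp98",
                         "anchor_value": 15102},
            scenarios=["i1_sp98", "i2_sp98", "i3_sp98"],
            out_dir=str(tmp_path),
        )
        run_reproduction(cfg, write=True)
        names = sorted(p.name for p in tmp_path.glob("*.csv"))
        assert names == [
            "comparisons.csv",
            "cumfp_base.csv",
            "cumfp_free50.csv",
            "cumfp_sensitivity.csv",
        ]


class TestZorziCheck:
    def test_no_attrition_upper_bound(self):
        flat = linear_survivorship(1.0, 1.0)
        assert zorzi_check(flat) == pytest.approx(1000 * (1 - 0.975**5), rel=1e-12)

    def test_perfect_specificity_gives_zero(self, calibrated_curve):
        assert zorzi_check(calibrated_curve, specificity=1.0) == 0.0

    def test_coverage_is_enforced(self):
        short = linear_survivorship(0.9, 0.8, start_age=50, stop_age=58)
        with pytest.raises(ValueError, match="cover"):
            zorzi_check(short)


class TestCli:
    def test_calibrate_prints_fitted_f50(self, calibrated_f50):
        result = CliRunner().invoke(main, ["calibrate"])
        assert result.exit_code == 0, result.output
        assert f"{calibrated_f50:.6f}" in result.output

    def test_run_command_writes_tables(self, tmp_path):
        result = CliRunner().invoke(main, ["run", "--out", str(tmp_path)])
        assert result.exit_code == 0, result.output
        assert (tmp_path / "cumfp_base.csv").exists()
        assert "i2_sp98" in result.output

    def test_zorzi_check_command(self):
        result = CliRunner().invoke(main, ["zorzi-check"])
        assert result.exit_code == 0, result.output
        assert "per 1000" in result.output

    def test_compare_command_accepts_pairs(self):
        result = CliRunner().invoke(main, ["compare", "i1_sp98:i2_sp98"])
        assert result.exit_code == 0, result.output
        assert "i1_sp98 vs i2_sp98" in result.output
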