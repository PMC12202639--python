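"""Comparison statistics, trend machinery, condition analysis and the
end-to-end pipeline (library and CLI)."""

import json

import numpy as np
import pytest
from click.testing import CliRunner

from ergoseat.cli import main as cli_main
from ergoseat.report import (
    ReportSchema,
    analyze_condition,
    compare_histograms,
    percent_deviation,
    run_pipeline,
    trend_similarity,
)
from ergoseat.synth import backrest_scenario, cushion_scenario, gen_pressure_map
from ergoseat.types import ComfortClass, ErgoseatError, InvariantError, PressureMap, RegionName


class TestPercentDeviation:
    @pytest.mark.parametrize("sim,exp,want", [
        (12.0, 10.0, 20.0), (10.0, 10.0, 0.0), (9.8, 10.0, 2.0),
    ])
    def test_examples(self, sim, exp, want):
        assert percent_deviation(sim, exp) == pytest.approx(want)

    def test_scale_invariance(self, rng):
        for _ in range(20):
            sim, exp = rng.uniform(0.1, 10, 2)
            c = rng.uniform(0.1, 5)
            assert percent_deviation(c * sim, c * exp) == pytest.approx(
                percent_deviation(sim, exp), rel=1e-12)

    def test_zero_experimental_rejected(self):
        with pytest.raises(InvariantError):
            percent_deviation(1.0, 0.0)


class TestHistogramComparison:
    def test_identical_and_disjoint(self):
        assert compare_histograms([3, 2, 1], [3, 2, 1])["tv_distance"] == 0.0
        assert compare_histograms([4, 0], [0, 4])["tv_distance"] == 1.0

    def test_hand_example(self):
        assert compare_histograms([2, 2], [1, 3])["tv_distance"] == pytest.approx(0.25)

    def test_mismatched_binning_rejected(self):
        with pytest.raises(InvariantError):
            compare_histograms([1, 2], [1, 2, 3])


class TestTrendSimilarity:
    def test_identical_reversed_and_hand_example(self):
        assert trend_similarity([1, 2, 3, 4, 5], [1, 2, 3, 4, 5]) == pytest.approx(1.0)
        assert trend_similarity([1, 2, 3, 4, 5], [5, 4, 3, 2, 1]) == pytest.approx(-1.0)
        # ranks of b differ from a by d = (0,1,1,1,1): rho = 1 - 6*4/120
        assert trend_similarity([1, 2, 3, 4, 5], [1, 3, 2, 5, 4]) == pytest.approx(0.8)

    def test_invariant_under_monotone_transform(self, rng):
        for _ in range(20):
            a = rng.normal(size=6)
            b = rng.normal(size=6)
            base = trend_similarity(a, b)
            assert trend_similarity(np.exp(a), b) == pytest.approx(base, abs=1e-12)
            assert trend_similarity(a, 3 * b + 7) == pytest.approx(base, abs=1e-12)

    def test_constant_series_rejected_not_nan(self):
        with pytest.raises(InvariantError, match="constant"):
            trend_similarity([1, 1, 1], [1, 2, 3])


class TestAnalyzeCondition:
    def test_four_region_blocks(self):
        res = analyze_condition(
            "whole_chair_flip", 10.0,
            cushion=gen_pressure_map(cushion_scenario(seed=1)),
            backrest=gen_pressure_map(backrest_scenario(seed=1)),
            cushion_split_row=14, backrest_l1_row=24)
        assert set(res.region_metrics) == {RegionName.HIP, RegionName.LEGS,
                                           RegionName.WAIST, RegionName.BACK}

    def test_waist_exceeding_window_flagged(self):
        grid = np.zeros((10, 10))
        grid[8, 5] = 8.55  # waist peak beyond the 4-8 kPa ideal window
        grid[2, 5] = 3.0
        res = analyze_condition(
            "backrest_flip", 20.0,
            backrest=PressureMap(grid, (10, 10), "backrest"), backrest_l1_row=4)
        assert res.comfort[RegionName.WAIST] == ComfortClass.ABOVE_IDEAL

    def test_requires_at_least_one_map(self):
        with pytest.raises(ErgoseatError):
            analyze_condition("backrest_flip", 0.0)


CONFIG = {
    "conditions": {"kind": "whole_chair_flip", "angles": [0, 10, 20, 30, 40],
                   "synthetic": {"seed": 7}},
    "partitions": {"cushion_split_row": 14, "backrest_l1_row": 24},
    "comparisons": [
        {"metric": "back_p_max", "simulated": 12.0, "experimental": 10.0},
    ],
}


class TestPipeline:
    def test_report_structure_and_schema(self, tmp_path):
        rep = run_pipeline(CONFIG, tmp_path / "out")
        ReportSchema.model_validate(rep)
        assert len(rep["conditions"]) == 5
        for block in rep["conditions"]:
            assert set(block["regions"]) == {"hip", "legs", "waist", "back"}
        # trend matrix covers every surface metric x internal response
        assert set(rep["trend_matrix"]) == {"hip", "legs", "waist", "back"}
        for metrics in rep["trend_matrix"].values():
            assert set(metrics) == {"p_max", "p_ave", "contact_area", "one_minus_spd"}
        assert rep["comparisons"][0]["percent_deviation"] == pytest.approx(20.0)
        assert (tmp_path / "out" / "metrics.csv").exists()
        assert (tmp_path / "out" / "trends.csv").exists()

    def test_reruns_byte_identical(self, tmp_path):
        run_pipeline(CONFIG, tmp_path / "a")
        run_pipeline(CONFIG, tmp_path / "b")
        assert (tmp_path / "a" / "report.json").read_bytes() == \
            (tmp_path / "b" / "report.json").read_bytes()

    def test_without_internal_tables_trends_restricted(self, tmp_path):
        import ergoseat.io as eio
        from ergoseat.synth import gen_condition_series
        series = gen_condition_series("backrest_flip", [-10, 0, 10, 20], seed=3)
        files = []
        for i, entry in enumerate(series):
            cpath = tmp_path / f"c{i}.csv"
            bpath = tmp_path / f"b{i}.csv"
            eio.write_pressure_map(entry["cushion"], cpath)
            eio.write_pressure_map(entry["backrest"], bpath)
            files.append({"angle": entry["angle"], "cushion": str(cpath),
                          "backrest": str(bpath)})
        cfg = {"conditions": {"kind": "backrest_flip", "files": files},
               "partitions": {"cushion_split_row": 14, "backrest_l1_row": 24}}
        rep = run_pipeline(cfg, tmp_path / "out")
        assert len(rep["conditions"]) == 4
        for metrics in rep["trend_matrix"].values():
            for row in metrics.values():
                assert row == {}  # no internal responses supplied

    def test_missing_file_fails_fast(self, tmp_path):
        cfg = {"conditions": {"kind": "backrest_flip", "files": [
            {"angle": 0, "cushion": str(tmp_path / "nope.csv")}]}}
        with pytest.raises(FileNotFoundError):
            run_pipeline(cfg, tmp_path / "out")


class TestCLI:
    def test_run_command_end_to_end(self, tmp_path):
        import yaml
        cfg_path = tmp_path / "study.yaml"
        cfg_path.write_text(yaml.safe_dump(CONFIG))
        runner = CliRunner()
        res = runner.invoke(cli_main, ["run", "--config", str(cfg_path),
                                       "--out", str(tmp_path / "rep")])
        assert res.exit_code == 0, res.output
        report = json.loads((tmp_path / "rep" / "report.json").read_text())
        assert len(report["conditions"]) == 5

    def test_metrics_command(self, tmp_path):
        import ergoseat.io as eio
        pmap = gen_pressure_map(cushion_scenario(seed=4))
        eio.write_pressure_map(pmap, tmp_path / "c.csv")
        runner = CliRunner()
        res = runner.invoke(cli_main, [
            "metrics", "--map", str(tmp_path / "c.csv"), "--interface", "cushion",
            "--split-row", "14"])
        assert res.exit_code == 0, res.output
        payload = json.loads(res.output)
        assert set(payload) == {"hip", "legs"}

    def test_spine_command(self, tmp_path):
        import ergoseat.io as eio
        from ergoseat.synth import gen_spine
        eio.write_spine(gen_spine(cc=15, ttk=35, ll=45), tmp_path / "s.csv")
        runner = CliRunner()
        res = runner.invoke(cli_main, ["spine", "--spine", str(tmp_path / "s.csv")])
        assert res.exit_code == 0, res.output
        payload = json.loads(res.output)
        assert payload["ll"] == pytest.approx(45.0, abs=1e-6)
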