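"""Model facade, end-to-end runs, fixture configs, and the CLI."""

import json

import pytest
from click.testing import CliRunner

from ssbsim import (RunConfig, SSBBanModel, build_fixture_world,
                    generate_fixture_configs, run_analysis)
from ssbsim.cli import main as cli_main
from ssbsim.population import ConfigError


@pytest.fixture(scope="module")
def fixture_dirs(tmp_path_factory):
    out = tmp_path_factory.mktemp("cfg")
    world = build_fixture_world()
    world.save(out / "world")
    return out


class TestModelOnFixtureWorld:
    def test_zero_discount_zero_mortality_closed_form(self):
        """No mortality, no discounting, no disutility: baseline QALYs equal
        n x horizon x baseline utility exactly."""
        world = build_fixture_world(disutility=0.0, discount_rate=0.0,
                                    baseline_utility=0.9)
        res = SSBBanModel(world, n_persons=250, n_replicates=2).fit(seed=4)
        base = res.baseline("employer")
        assert base["qalys"] == pytest.approx(10 * 0.9 * 10_000)
        assert base["qalys_discounted"] == pytest.approx(10 * 0.9 * 10_000)

    def test_null_relative_risk_saves_nothing(self):
        world = build_fixture_world(rr=1.0)
        res = SSBBanModel(world, n_persons=250, n_replicates=2).fit(seed=4)
        assert res.qalys_saved("employer") == 0.0
        assert res.dollars_saved("employer") == 0.0

    def test_averted_cases_match_cohort_closed_form(self):
        """Fixture world: averted-case fraction matches the two-state chain."""
        h, rr, years, n = 0.05, 0.9, 10, 20_000
        world = build_fixture_world(incidence=h, rr=rr)
        res = SSBBanModel(world, n_persons=n, n_replicates=4,
                          resample_population=False).fit(seed=6)
        red = res.incidence_reductions()["diabetes"] / 100
        expected = 1 - (1 - (1 - h * rr) ** years) / (1 - (1 - h) ** years)
        assert red == pytest.approx(expected, abs=0.015)

    def test_summary_mentions_key_quantities(self, calibrated_world):
        res = SSBBanModel(calibrated_world, n_persons=300, n_replicates=2).fit(seed=1)
        text = res.summary()
        assert "QALYs saved" in text and "per 10,000" in text

    def test_subgroup_table_covers_groups(self, calibrated_world):
        res = SSBBanModel(calibrated_world, n_persons=500, n_replicates=2).fit(seed=1)
        tab = res.by_group("race_ethnicity")
        assert set(tab.index) == {"white", "black", "hispanic", "asian"}


class TestRunAnalysis:
    def test_smoke_bundle_complete(self, fixture_dirs, tmp_path):
        cfg = RunConfig(world_dir=str(fixture_dirs / "world"),
                        output_dir=str(tmp_path / "out"),
                        n_persons=100, n_replicates=2, seed=3)
        written = run_analysis(cfg)
        for key in ("scenario_result", "exhibit1", "manifest"):
            assert key in written
        bundle = json.loads(open(written["scenario_result"]).read())
        assert bundle["n_persons"] == 100
        manifest = json.loads(open(written["manifest"]).read())
        assert manifest["seed"] == 3 and "config_hash" in manifest

    def test_same_seed_byte_identical_outputs(self, fixture_dirs, tmp_path):
        blobs = []
        for run_dir in ("a", "b"):
            cfg = RunConfig(world_dir=str(fixture_dirs / "world"),
                            output_dir=str(tmp_path / run_dir),
                            n_persons=100, n_replicates=2, seed=9)
            written = run_analysis(cfg)
            blobs.append(open(written["scenario_result"], "rb").read())
        assert blobs[0] == blobs[1]

    def test_schema_violation_reported_before_simulation(self, tmp_path):
        cfg = RunConfig(world_dir=str(tmp_path / "missing"),
                        output_dir=str(tmp_path / "out"))
        with pytest.raises(ConfigError, match="missing input file"):
            run_analysis(cfg)

    def test_exhibit_totals_equal_category_sums(self, fixture_dirs, tmp_path):
        import pandas as pd
        cfg = RunConfig(world_dir=str(fixture_dirs / "world"),
                        output_dir=str(tmp_path / "out"),
                        n_persons=200, n_replicates=2, seed=5)
        written = run_analysis(cfg)
        ex = pd.read_csv(written["exhibit1"])
        for persp, grp in ex.groupby("perspective"):
            total = grp[grp.category == "total"]
            parts = grp[grp.category != "total"]
            assert parts.qalys_saved.sum() == pytest.approx(
                float(total.qalys_saved.iloc[0]), abs=1e-6)
            assert parts.dollars_saved.sum() == pytest.approx(
                float(total.dollars_saved.iloc[0]), abs=1e-4)


class TestCLI:
    def test_simulate_and_validate(self, fixture_dirs, tmp_path):
        runner = CliRunner()
        result = runner.invoke(cli_main, [
            "simulate", "--world", str(fixture_dirs / "world"),
            "--output", str(tmp_path / "cli_out"),
            "--persons", "100", "--replicates", "2", "--seed", "1"])
        assert result.exit_code == 0, result.output
        assert (tmp_path / "cli_out" / "scenario_result.json").exists()

    def test_validate_config_rejects_broken_config(self, fixture_dirs, tmp_path):
        import yaml
        cfg = RunConfig(world_dir=str(fixture_dirs / "world"),
                        output_dir=str(tmp_path / "o"), scenario="base")
        raw = cfg.to_yaml_dict()
        raw["scenario"] = "nonsense"
        path = tmp_path / "bad.yaml"
        with open(path, "w") as f:
            yaml.safe_dump(raw, f)
        runner = CliRunner()
        result = runner.invoke(cli_main, ["validate-config", str(path)])
        assert result.exit_code != 0
        assert "scenario" in result.output

    def test_generate_fixture_configs_bundle(self, tmp_path):
        written = generate_fixture_configs(tmp_path)
        assert (tmp_path / "fixture_world" / "world.yaml").exists()
        assert (tmp_path / "calibrated_world" / "world.yaml").exists()
        for key in ("fixture_run", "calibrated_run"):
            cfg = RunConfig.from_yaml(written[key])
            cfg.validate()
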