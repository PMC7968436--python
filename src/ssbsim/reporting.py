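"""End-to-end run orchestration: config validation, output bundles, manifests.

`run_analysis` drives a complete analysis from a single run configuration:
it validates every referenced table before simulating, runs the paired
Monte Carlo model, and writes scenario-result JSON, exhibit-style CSV
tables, subgroup ratio tables, optional break-even outputs, a run manifest
(config hash, seed, package version), and a structured log.  Partial
outputs are removed if the run fails.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibration import build_fixture_world, build_calibrated_world
from .model import SSBBanModel
from .population import ConfigError
from .world import World

logger = logging.getLogger("ssbsim")


@dataclass
class RunConfig:
    """Settings for one end-to-end analysis run."""

    world_dir: str                     # directory with world.yaml + tables
    output_dir: str
    n_persons: int = 10_000
    n_replicates: int = 50
    seed: int = 1
    scenario: str = "base"             # 'base' (full offset) or 'no_offset'
    run_breakeven: bool = False
    breakeven_bounds: tuple = (0.05, 8.0)
    breakeven_tolerance_usd: float = 100.0
    group_by: tuple = ("race_ethnicity", "occupational_class")

    def validate(self) -> None:
        if self.n_persons < 1 or self.n_replicates < 1:
            raise ConfigError("run config: n_persons and n_replicates must be >= 1")
        if self.scenario not in ("base", "no_offset"):
            raise ConfigError(f"run config: unknown scenario '{self.scenario}'")
        p = Path(self.world_dir)
        for f in ("world.yaml", "rates.csv", "costs.csv", "utilities.csv"):
            if not (p / f).exists():
                raise ConfigError(f"run config: missing input file {p / f}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            raw = yaml.safe_load(f)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"run config: unknown fields {sorted(unknown)}")
        if "breakeven_bounds" in raw:
            raw["breakeven_bounds"] = tuple(raw["breakeven_bounds"])
        if "group_by" in raw:
            raw["group_by"] = tuple(raw["group_by"])
        return cls(**raw)

    def to_yaml_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["breakeven_bounds"] = list(self.breakeven_bounds)
        d["group_by"] = list(self.group_by)
        return d


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_yaml_dict(), sort_keys=True).encode()
    for name in ("world.yaml", "rates.csv", "costs.csv", "utilities.csv"):
        blob += (Path(config.world_dir) / name).read_bytes()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_analysis(config: RunConfig) -> dict:
    """Execute a full analysis; returns a dict of written file paths.

    Outputs are byte-reproducible given the same configuration and seed.
    """
    config.validate()
    world = World.load(config.world_dir)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, str] = {}

    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        logger.info("run start: n=%d replicates=%d seed=%d scenario=%s",
                    config.n_persons, config.n_replicates, config.seed,
                    config.scenario)
        model = SSBBanModel(world, n_persons=config.n_persons,
                            n_replicates=config.n_replicates)
        results = model.fit(seed=config.seed)
        logger.info("simulation complete")

        bundle = results.to_json_dict()
        bundle["scenario"] = config.scenario
        if config.scenario == "no_offset":
            bundle["sales_loss"] = results.sales_loss(no_offset=True)
            bundle["icer"] = results.icer_no_offset()
        _write_json(out / "scenario_result.json", bundle)
        written["scenario_result"] = str(out / "scenario_result.json")

        exhibit = results.exhibit1()
        exhibit.to_csv(out / "exhibit1.csv", index=False)
        written["exhibit1"] = str(out / "exhibit1.csv")

        for group in config.group_by:
            tab = results.by_group(group)
            # ratio table: group saving per 10,000 relative to overall
            overall = results.qalys_saved("healthcare")
            tab["qalys_saved_ratio"] = tab["qalys_saved"] / overall
            overall_c = results.dollars_saved("healthcare")
            tab["dollars_saved_ratio"] = tab["dollars_saved"] / overall_c
            name = f"subgroups_{group}.csv"
            tab.to_csv(out / name)
            written[f"subgroups_{group}"] = str(out / name)

        if config.run_breakeven:
            logger.info("break-even search")
            be = results.breakeven(lo=config.breakeven_bounds[0],
                                   hi=config.breakeven_bounds[1],
                                   tolerance_usd=config.breakeven_tolerance_usd)
            _write_json(out / "breakeven.json", be.to_json_dict())
            be.curve.to_csv(out / "breakeven_curve.csv", index=False)
            written["breakeven"] = str(out / "breakeven.json")
            written["breakeven_curve"] = str(out / "breakeven_curve.csv")

        from . import __version__
        manifest = {
            "config": config.to_yaml_dict(),
            "config_hash": _config_hash(config),
            "seed": config.seed,
            "ssbsim_version": __version__,
            "numpy_version": np.__version__,
            "pandas_version": pd.__version__,
        }
        _write_json(out / "manifest.json", manifest)
        written["manifest"] = str(out / "manifest.json")
        logger.info("run complete: %d outputs", len(written))
        return written
    except Exception:
        logger.exception("run failed; removing partial outputs")
        for path in written.values():
            Path(path).unlink(missing_ok=True)
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()


def _write_json(path: Path, obj: dict) -> None:
    with open(path, "w") as f:
        json.dump(obj, f, indent=2, sort_keys=True, default=float)
        f.write("\n")


def generate_fixture_configs(out_dir) -> dict[str, str]:
    """Emit a tiny deterministic test world and a target-calibrated world.

    The fixture world has one active disease with constant rates, so every
    output has a closed form; the second is the calibrated
    bundle whose parameters reproduce the published summary targets.
    """
    out = Path(out_dir)
    fixture = build_fixture_world()
    fixture.save(out / "fixture_world")
    calibrated = build_calibrated_world()
    calibrated.save(out / "calibrated_world")
    for name, world_dir in (("fixture", "fixture_world"), ("calibrated", "calibrated_world")):
        cfg = RunConfig(world_dir=str(out / world_dir),
                        output_dir=str(out / f"{name}_results"),
                        n_persons=100 if name == "fixture" else 10_000,
                        n_replicates=2 if name == "fixture" else 50)
        with open(out / f"{name}_run.yaml", "w") as f:
            yaml.safe_dump(cfg.to_yaml_dict(), f, sort_keys=False)
    return {"fixture_world": str(out / "fixture_world"),
            "calibrated_world": str(out / "calibrated_world"),
            "fixture_run": str(out / "fixture_run.yaml"),
            "calibrated_run": str(out / "calibrated_run.yaml")}
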