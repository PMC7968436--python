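"""The full configuration bundle ("world") consumed by a simulation run.

A world packages every model input: demographics, disease schedules,
background mortality, the intervention-effect distribution, per-outcome
effect sizes, utilities, costs, economic assumptions, and sales parameters.
Worlds round-trip to a directory of plain-text files: a `world.yaml` main
configuration plus CSV rate/utility/cost tables.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .economics import CostTable, EconomicAssumptions, UtilityTable
from .engine import BackgroundMortality, DiseaseModel, EmploymentModel, RateTable
from .intervention import EffectSizeTable, InterventionEffect, OutcomeEffect
from .population import (AgeBands, CONDITIONS, ConfigError, DemographicsConfig,
                         GammaSSB, TruncLognormBMI)

SCHEMA_VERSION = 1


def _to_builtin(obj):
    """Recursively coerce numpy scalars/arrays to YAML-safe built-ins."""
    import numpy as np
    if isinstance(obj, dict):
        return {k: _to_builtin(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_builtin(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


@dataclass
class World:
    """Complete, validated input bundle for the microsimulation."""

    demographics: DemographicsConfig
    diseases: dict[str, DiseaseModel]
    background: BackgroundMortality
    effect: InterventionEffect
    effect_sizes: EffectSizeTable
    utilities: UtilityTable
    costs: CostTable
    econ: EconomicAssumptions
    sales: "SalesAssumptions"
    meta: dict = field(default_factory=dict)

    def validate(self) -> None:
        self.demographics.validate()
        missing = [c for c in CONDITIONS if c not in self.diseases]
        if missing:
            raise ConfigError(f"diseases: missing models for {missing}")
        for dm in self.diseases.values():
            dm.validate()
        self.effect.validate()
        self.effect_sizes.validate()
        self.utilities.validate()
        self.costs.validate()
        self.econ.validate()
        self.sales.validate()

    @property
    def employment(self) -> EmploymentModel:
        return EmploymentModel(annual_attrition_rate=self.econ.annual_attrition_rate,
                               retirement_age=self.econ.retirement_age)

    # ------------------------------------------------------------------ IO
    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        rate_rows = []
        for cond, dm in self.diseases.items():
            for r in dm.annual_incidence.to_records(cond):
                rate_rows.append(dict(r, kind="incidence"))
            for r in dm.case_fatality.to_records(cond):
                rate_rows.append(dict(r, kind="case_fatality"))
        for r in self.background.table.to_records("background"):
            rate_rows.append(dict(r, kind="mortality"))
        pd.DataFrame(rate_rows).to_csv(d / "rates.csv", index=False)

        pd.DataFrame([
            {"outcome": c,
             "annual_health_cost": self.costs.annual_health_cost.get(c, 0.0),
             "annual_health_cost_postretirement":
                 self.costs.health_cost_postretirement(c),
             "annual_productivity_cost": self.costs.annual_productivity_cost.get(c, 0.0)}
            for c in CONDITIONS]).to_csv(d / "costs.csv", index=False)

        util_rows = [{"outcome": c, "disutility": self.utilities.disutilities.get(c, 0.0),
                      "bmi_lo": "", "bmi_hi": ""} for c in CONDITIONS if c != "obesity"]
        for lo, hi, du in self.utilities.obesity_disutility_by_bmi:
            util_rows.append({"outcome": "obesity", "disutility": du,
                              "bmi_lo": lo, "bmi_hi": hi})
        pd.DataFrame(util_rows).to_csv(d / "utilities.csv", index=False)

        dem = self.demographics
        cfg = {
            "schema_version": SCHEMA_VERSION,
            "tables": {"rates": "rates.csv", "costs": "costs.csv",
                       "utilities": "utilities.csv"},
            "demographics": {
                "age_distribution": {"edges": [float(e) for e in dem.age_distribution.edges],
                                     "weights": [float(w) for w in dem.age_distribution.weights]},
                "sex_fractions": dict(dem.sex_fractions),
                "race_ethnicity_fractions": dict(dem.race_ethnicity_fractions),
                "occupational_class_fractions": dict(dem.occupational_class_fractions),
                "insurance_coverage_rate": dem.insurance_coverage_rate,
                "baseline_prevalence_by_condition": {
                    k: float(v) for k, v in dem.baseline_prevalence_by_condition.items()},
                "bmi_distribution": dataclasses.asdict(dem.bmi_distribution),
                "ssb_consumption_distribution": dataclasses.asdict(
                    dem.ssb_consumption_distribution),
                "ssb_multiplier_by_occupation": dict(dem.ssb_multiplier_by_occupation),
            },
            "disease_flags": {c: {
                "remission_allowed": self.diseases[c].remission_allowed,
                "contributes_to_mortality": self.diseases[c].contributes_to_mortality,
            } for c in CONDITIONS},
            "intervention_effect": dataclasses.asdict(self.effect),
            "effect_sizes": {
                "reference_reduction": self.effect_sizes.reference_reduction,
                "subgroup_multipliers": dict(self.effect_sizes.subgroup_multipliers),
                "outcomes": {name: {
                    "rr_at_reference": e.rr_at_reference,
                    "applies_to": list(e.applies_to),
                    "rr_burden_at_reference": e.rr_burden_at_reference,
                    "rr_disutility_at_reference": e.rr_disutility_at_reference}
                             for name, e in self.effect_sizes.effects.items()},
            },
            "utilities": {
                "baseline_utility": self.utilities.baseline_utility,
                "baseline_utility_age_slope": self.utilities.baseline_utility_age_slope,
                "age_anchor": self.utilities.age_anchor},
            "costs": {"death_productivity_cost": self.costs.death_productivity_cost,
                      "cpi_factor_to_dec2019": self.costs.cpi_factor_to_dec2019},
            "economics": dataclasses.asdict(self.econ),
            "sales": dataclasses.asdict(self.sales),
            "meta": self.meta,
        }
        with open(d / "world.yaml", "w") as f:
            yaml.safe_dump(_to_builtin(cfg), f, sort_keys=False)

    @classmethod
    def load(cls, directory) -> "World":
        from .sensitivity import SalesAssumptions
        d = Path(directory)
        with open(d / "world.yaml") as f:
            cfg = yaml.safe_load(f)
        if cfg.get("schema_version") != SCHEMA_VERSION:
            raise ConfigError(
                f"world.yaml: unsupported schema_version {cfg.get('schema_version')}")
        dm_cfg = cfg["demographics"]
        demographics = DemographicsConfig(
            age_distribution=AgeBands(**dm_cfg["age_distribution"]),
            sex_fractions=dm_cfg["sex_fractions"],
            race_ethnicity_fractions=dm_cfg["race_ethnicity_fractions"],
            occupational_class_fractions=dm_cfg["occupational_class_fractions"],
            insurance_coverage_rate=dm_cfg["insurance_coverage_rate"],
            baseline_prevalence_by_condition=dm_cfg["baseline_prevalence_by_condition"],
            bmi_distribution=TruncLognormBMI(**dm_cfg["bmi_distribution"]),
            ssb_consumption_distribution=GammaSSB(**dm_cfg["ssb_consumption_distribution"]),
            ssb_multiplier_by_occupation=dm_cfg.get("ssb_multiplier_by_occupation", {}),
        )
        rates = pd.read_csv(d / cfg["tables"]["rates"])
        diseases = {}
        for c in CONDITIONS:
            flags = cfg["disease_flags"][c]
            inc = rates[(rates.outcome == c) & (rates.kind == "incidence")]
            cf = rates[(rates.outcome == c) & (rates.kind == "case_fatality")]
            diseases[c] = DiseaseModel(
                name=c,
                annual_incidence=RateTable(inc.to_dict(orient="records")),
                case_fatality=RateTable(cf.to_dict(orient="records")),
                remission_allowed=flags["remission_allowed"],
                contributes_to_mortality=flags["contributes_to_mortality"])
        bg = rates[(rates.outcome == "background") & (rates.kind == "mortality")]
        background = BackgroundMortality(RateTable(bg.to_dict(orient="records")))

        costs_df = pd.read_csv(d / cfg["tables"]["costs"])
        costs = CostTable(
            annual_health_cost=dict(zip(costs_df.outcome, costs_df.annual_health_cost)),
            annual_productivity_cost=dict(zip(costs_df.outcome,
                                              costs_df.annual_productivity_cost)),
            annual_health_cost_postretirement=dict(zip(
                costs_df.outcome, costs_df.annual_health_cost_postretirement)),
            death_productivity_cost=cfg["costs"]["death_productivity_cost"],
            cpi_factor_to_dec2019=cfg["costs"]["cpi_factor_to_dec2019"])

        util_df = pd.read_csv(d / cfg["tables"]["utilities"])
        disutils, bands = {}, []
        for _, row in util_df.iterrows():
            if row.outcome == "obesity":
                bands.append((float(row.bmi_lo), float(row.bmi_hi), float(row.disutility)))
            else:
                disutils[row.outcome] = float(row.disutility)
        utilities = UtilityTable(
            baseline_utility=cfg["utilities"]["baseline_utility"],
            disutilities=disutils,
            obesity_disutility_by_bmi=tuple(bands),
            baseline_utility_age_slope=cfg["utilities"].get(
                "baseline_utility_age_slope", 0.0),
            age_anchor=cfg["utilities"].get("age_anchor", 40.0))

        es = cfg["effect_sizes"]
        effect_sizes = EffectSizeTable(
            effects={name: OutcomeEffect(
                rr_at_reference=v["rr_at_reference"],
                applies_to=tuple(v["applies_to"]),
                rr_burden_at_reference=v.get("rr_burden_at_reference"),
                rr_disutility_at_reference=v.get("rr_disutility_at_reference"))
                     for name, v in es["outcomes"].items()},
            reference_reduction=es["reference_reduction"],
            subgroup_multipliers=es.get("subgroup_multipliers", {}))

        world = cls(demographics=demographics, diseases=diseases, background=background,
                    effect=InterventionEffect(**cfg["intervention_effect"]),
                    effect_sizes=effect_sizes, utilities=utilities, costs=costs,
                    econ=EconomicAssumptions(**cfg["economics"]),
                    sales=SalesAssumptions(**cfg["sales"]),
                    meta=cfg.get("meta", {}))
        world.validate()
        return world
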