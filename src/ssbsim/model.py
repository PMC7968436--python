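"""Model/results facade for end-to-end cost-effectiveness runs.

`SSBBanModel` bundles a world (input configuration) with run settings; its
`fit()` executes the paired Monte Carlo microsimulation and returns an
`SSBBanResults` object carrying estimates, percentile confidence intervals,
decompositions, and the sensitivity analyses (sales loss, ICER, break-even).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .economics import (EconRecorder, ScenarioResult, aggregate_results,
                        discount_factor)
from .engine import EventWindowRecorder, ReplicateResult, run_paired_scenarios
from .population import CONDITIONS, CONDITION_LABELS, Population, generate_population
from .sensitivity import BreakEvenResult, find_breakeven_reduction, icer_with_ci
from .world import World


class SSBBanModel:
    """Workplace SSB sales-ban cost-effectiveness microsimulation.

    Parameters
    ----------
    world
        Complete input bundle (demographics, disease schedules, effect
        sizes, utilities, costs, economics, sales).
    n_persons
        Simulated employees per replicate.
    n_replicates
        Monte Carlo replicates; each draws one effect-size reduction and a
        fresh population sample, then simulates ban and control arms under
        common random numbers.
    """

    def __init__(self, world: World, n_persons: int = 10_000,
                 n_replicates: int = 50, resample_population: bool = True):
        world.validate()
        if n_persons < 1 or n_replicates < 1:
            raise ValueError("n_persons and n_replicates must be >= 1")
        self.world = world
        self.n_persons = n_persons
        self.n_replicates = n_replicates
        self.resample_population = resample_population

    @classmethod
    def from_calibration(cls, targets=None, n_persons: int = 10_000,
                         n_replicates: int = 50, **kwargs) -> "SSBBanModel":
        from .calibration import build_calibrated_world
        return cls(build_calibrated_world(targets), n_persons=n_persons,
                   n_replicates=n_replicates, **kwargs)

    @classmethod
    def from_config_dir(cls, directory, **kwargs) -> "SSBBanModel":
        return cls(World.load(directory), **kwargs)

    # ------------------------------------------------------------------
    def _population_source(self, seed: int):
        if self.resample_population:
            return lambda s: generate_population(self.n_persons,
                                                 self.world.demographics, s)
        return generate_population(self.n_persons, self.world.demographics, seed)

    def _recorder_factory(self):
        w = self.world

        def factory(arm: str, pop: Population):
            return (EconRecorder(pop, w.utilities, w.costs, w.econ),
                    EventWindowRecorder(w.econ.employer_horizon))
        return factory

    def fit(self, seed: int = 1) -> "SSBBanResults":
        """Run paired lifetime simulations and aggregate both perspectives."""
        w = self.world
        replicates = run_paired_scenarios(
            self._population_source(seed), w.diseases, w.background,
            w.effect_sizes, w.effect, "lifetime", self.n_replicates, seed,
            employment=w.employment, recorder_factory=self._recorder_factory(),
            exposure=w.meta.get("exposure", "while_employed"))
        employer = aggregate_results(
            replicates, w.utilities, w.costs,
            dataclasses.replace(w.econ, perspective="employer"),
            horizon="employer")
        healthcare = aggregate_results(
            replicates, w.utilities, w.costs,
            dataclasses.replace(w.econ, perspective="healthcare"),
            horizon="lifetime")
        return SSBBanResults(model=self, seed=seed, replicates=replicates,
                             employer=employer, healthcare=healthcare)


@dataclass
class SSBBanResults:
    """Fitted results: decompositions, baselines, and sensitivity analyses."""

    model: SSBBanModel
    seed: int
    replicates: list[ReplicateResult]
    employer: ScenarioResult
    healthcare: ScenarioResult

    # ------------------------------------------------------------ accessors
    @property
    def world(self) -> World:
        return self.model.world

    def result(self, perspective: str) -> ScenarioResult:
        if perspective == "employer":
            return self.employer
        if perspective == "healthcare":
            return self.healthcare
        raise ValueError(f"unknown perspective '{perspective}'")

    def qalys_saved(self, perspective: str = "employer") -> float:
        return float(self.result(perspective).table.loc["total", "qalys_saved"])

    def dollars_saved(self, perspective: str = "employer") -> float:
        return float(self.result(perspective).table.loc["total", "dollars_saved"])

    def baseline(self, perspective: str = "employer") -> dict[str, float]:
        """No-ban arm totals per 10,000 (QALYs undiscounted, costs discounted)."""
        rows = self.result(perspective).per_replicate
        out = {}
        for key, col in (("qalys", "baseline_qalys_undisc"),
                         ("qalys_discounted", "baseline_qalys_disc"),
                         ("person_years", "baseline_py_undisc"),
                         ("cost", "baseline_cost_total")):
            v = rows[col].to_numpy()
            out[key] = float(v.mean())
            out[f"{key}_ci_lo"] = float(np.percentile(v, 2.5))
            out[f"{key}_ci_hi"] = float(np.percentile(v, 97.5))
        out["qalys_per_person_year"] = out["qalys"] / out["person_years"]
        return out

    def incidence_reductions(self, per_replicate: bool = False
                             ) -> pd.Series | pd.DataFrame:
        """Percent reduction in incidence+mortality per outcome (10y window).

        The default pools events over replicates; `per_replicate=True`
        returns one row per replicate (for Monte Carlo standard errors).
        """
        rows = []
        for rep in self.replicates:
            ctl = rep.control.recorders[1]
            ban = rep.ban.recorders[1]
            ev_c, ev_b = ctl.events(), ban.events()
            rows.append({
                **{c: (ev_c[k], ev_b[k]) for k, c in enumerate(CONDITIONS)},
                "other_mortality": (ctl.other_deaths, ban.other_deaths)})
        if per_replicate:
            out = pd.DataFrame([
                {name: (100.0 * (1.0 - b / c) if c > 0 else np.nan)
                 for name, (c, b) in row.items()} for row in rows])
            return out
        pooled = {}
        for name in list(CONDITIONS) + ["other_mortality"]:
            c = sum(row[name][0] for row in rows)
            b = sum(row[name][1] for row in rows)
            pooled[name] = 100.0 * (1.0 - b / c) if c > 0 else np.nan
        return pd.Series(pooled, name="incidence_reduction_pct")

    def by_group(self, group_by: str, perspective: str = "healthcare"
                 ) -> pd.DataFrame:
        """Subgroup QALYs/dollars saved per 10,000 (race or occupation)."""
        w = self.world
        econ = dataclasses.replace(w.econ, perspective=perspective)
        horizon = "lifetime" if perspective == "healthcare" else "employer"
        res = aggregate_results(self.replicates, w.utilities, w.costs, econ,
                                horizon=horizon, group_by=group_by)
        return res.by_group

    # ------------------------------------------------------- sensitivity
    def _replicate_losses(self, no_offset: bool = True) -> np.ndarray:
        w = self.world
        sales = dataclasses.replace(
            w.sales, compensatory_offset_fraction=0.0 if no_offset
            else w.sales.compensatory_offset_fraction)
        losses = np.array([
            _sales_loss_from_arrays(rep.ban.state.ssb, _initial_ages(rep),
                                    rep.reduction, sales, w.econ)
            for rep in self.replicates])
        return losses * _price_multipliers(self.replicates, sales)

    def sales_loss(self, no_offset: bool = True) -> dict[str, float]:
        """Discounted uncompensated SSB revenue loss per 10,000 (mean, CI)."""
        losses = self._replicate_losses(no_offset)
        return {"loss": float(losses.mean()),
                "ci_lo": float(np.percentile(losses, 2.5)),
                "ci_hi": float(np.percentile(losses, 97.5))}

    def icer_no_offset(self) -> dict[str, float]:
        """Employer-perspective ICER when sales losses are uncompensated.

        Net cost = sales loss minus averted health/productivity spending;
        divided by QALYs saved.  Negative values mean the ban dominates.
        """
        losses = self._replicate_losses(no_offset=True)
        rows = self.employer.per_replicate
        net_cost = losses - rows["cost_saved_total"].to_numpy()
        dq = rows["qalys_saved_total"].to_numpy()
        return icer_with_ci(net_cost, dq)

    def breakeven(self, lo: float = 0.05, hi: float = 8.0,
                  tolerance_usd: float = 100.0,
                  n_replicates: int | None = None) -> BreakEvenResult:
        """Consumption reduction where discounted savings equal sales losses.

        Rescans the model at forced reduction levels (employer horizon,
        common random numbers, uncompensated losses) and bisects the mean
        savings-minus-loss curve; per-replicate roots give the CI.
        """
        w = self.model.world
        n_rep = n_replicates or self.model.n_replicates
        sales0 = dataclasses.replace(w.sales, compensatory_offset_fraction=0.0)
        econ_emp = dataclasses.replace(w.econ, perspective="employer")
        seed = self.seed
        loss_mults = _price_multipliers(self.replicates[:n_rep], sales0)

        def savings_fn(r: float) -> np.ndarray:
            reps = run_paired_scenarios(
                self.model._population_source(seed), w.diseases, w.background,
                w.effect_sizes, w.effect, w.econ.employer_horizon, n_rep, seed,
                employment=w.employment,
                recorder_factory=self.model._recorder_factory(),
                forced_reduction=r,
                exposure=w.meta.get("exposure", "while_employed"))
            res = aggregate_results(reps, w.utilities, w.costs, econ_emp,
                                    horizon="employer")
            return res.per_replicate["cost_saved_total"].to_numpy()

        def loss_fn(r: float) -> np.ndarray:
            base = np.array([
                _sales_loss_from_arrays(rep.ban.state.ssb, _initial_ages(rep),
                                        r, sales0, w.econ)
                for rep in self.replicates[:n_rep]])
            return base * loss_mults

        return find_breakeven_reduction(savings_fn, loss_fn, lo=lo, hi=hi,
                                        tolerance_usd=tolerance_usd)

    # ------------------------------------------------------------ reporting
    def exhibit1(self) -> pd.DataFrame:
        """Exhibit-style table: QALYs and dollars saved by outcome, both
        perspectives (employer 10-year, health care lifetime)."""
        frames = []
        for persp, res in (("employer_10y", self.employer),
                           ("healthcare_lifetime", self.healthcare)):
            t = res.table.copy()
            t.insert(0, "perspective", persp)
            t.insert(1, "outcome", [CONDITION_LABELS.get(c, c.replace("_", " "))
                                    for c in t.index])
            frames.append(t.reset_index(names="category"))
        return pd.concat(frames, ignore_index=True)

    def summary(self) -> str:
        b_emp = self.baseline("employer")
        b_hc = self.baseline("healthcare")
        red = self.incidence_reductions()
        lines = [
            "Workplace SSB sales-ban microsimulation",
            "=" * 64,
            f"persons/replicate: {self.model.n_persons:>8,d}"
            f"    replicates: {self.model.n_replicates}",
            f"mean reduction draw: "
            f"{np.mean([r.reduction for r in self.replicates]):.2f} oz/person/day",
            "",
            "Baseline (no ban), per 10,000:",
            f"  employer 10y:  {b_emp['qalys']:>12,.0f} QALYs"
            f"   ${b_emp['cost']:>14,.0f} costs",
            f"  healthcare lifetime: {b_hc['qalys']:>8,.0f} QALYs"
            f"   ${b_hc['cost']:>14,.0f} costs",
            "",
            "Intervention effect (ban vs control), per 10,000 (discounted):",
            f"  employer 10y:   {self.qalys_saved('employer'):>8.1f} QALYs saved"
            f"   ${self.dollars_saved('employer'):>12,.0f} saved",
            f"  healthcare lifetime: {self.qalys_saved('healthcare'):>6.1f} QALYs"
            f" saved   ${self.dollars_saved('healthcare'):>12,.0f} saved",
            "",
            "Incidence+mortality reductions (10y): "
            + ", ".join(f"{c} {v:.1f}%" for c, v in red.items()),
        ]
        return "\n".join(lines)

    def to_json_dict(self) -> dict:
        return {
            "seed": self.seed,
            "n_persons": self.model.n_persons,
            "n_replicates": self.model.n_replicates,
            "baseline_employer": self.baseline("employer"),
            "baseline_healthcare": self.baseline("healthcare"),
            "employer": self.employer.to_json_dict(),
            "healthcare": self.healthcare.to_json_dict(),
            "incidence_reductions_pct": self.incidence_reductions().to_dict(),
        }


def _initial_ages(rep: ReplicateResult) -> np.ndarray:
    # baseline ages (SimState ages advance during simulation)
    return rep.ban.recorders[0]._baseline_ages


def _sales_loss_from_arrays(ssb: np.ndarray, age: np.ndarray, reduction: float,
                            sales, econ, scale_to: float = 10000.0) -> float:
    atwork = sales.work_fraction_of_consumption * ssb
    oz = np.minimum(reduction, atwork)
    annual = (oz * sales.price_per_oz * sales.employer_profit_fraction
              * sales.workdays_per_year * (1.0 - sales.compensatory_offset_fraction))
    total = 0.0
    for t in range(econ.employer_horizon):
        employed = (age + t) < econ.retirement_age
        weight = (1.0 - econ.annual_attrition_rate) ** t
        total += discount_factor(t, econ.discount_rate) * weight * float(annual[employed].sum())
    return total * scale_to / len(ssb)


def _price_multipliers(replicates, sales) -> np.ndarray:
    if sales.price_uncertainty_cv <= 0:
        return np.ones(len(replicates))
    cv = sales.price_uncertainty_cv
    sigma = np.sqrt(np.log1p(cv ** 2))
    return np.array([
        np.exp(np.random.default_rng(np.random.SeedSequence(
            entropy=int(rep.param_seed), spawn_key=(1,))).normal(-sigma ** 2 / 2, sigma))
        for rep in replicates])
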