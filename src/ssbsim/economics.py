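"""Valuation of trajectories: discounted QALYs and costs by category and payer.

Utilities combine additively: a person-year's QALY weight is the baseline
utility minus the disutilities of active conditions (obesity via a BMI-band
table), floored at zero.  The year of death contributes a half cycle at the
start-of-year state; full years are credited otherwise.

Costs per prevalent condition-year split into health-care spending (payer =
employer share while enrolled and below retirement age, employee/public
otherwise, including post-retirement Medicare) and productivity losses
(absenteeism, presenteeism, disability), which accrue only while employed.
A one-time premature-death productivity cost applies to deaths before
retirement age.  All dollars are constant December-2019 USD; CPI inflation
factors are applied to cost tables at load time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .engine import N_COND, YearRecord, ReplicateResult, SimState
from .population import CONDITIONS, ConfigError

#: decomposition row labels: six outcomes, the other-cause-mortality channel, total
CATEGORIES = list(CONDITIONS) + ["other_mortality"]


def discount_factor(year: int | np.ndarray, rate: float) -> float | np.ndarray:
    """Present-value factor (1+rate)^(-year); cycle 0 is undiscounted."""
    year_arr = np.asarray(year)
    if np.any(year_arr < 0):
        raise ValueError("discount_factor: year must be nonnegative")
    out = (1.0 + rate) ** (-year_arr.astype(float))
    return float(out) if out.ndim == 0 else out


@dataclass
class UtilityTable:
    """Baseline utility and per-condition annual disutilities.

    Baseline utility may decline linearly with age (population-norm utility
    decline independent of the modeled conditions); the slope is the
    per-year decrement beyond `age_anchor`.
    """

    baseline_utility: float = 0.76
    disutilities: Mapping[str, float] = field(default_factory=dict)
    # BMI-band obesity disutility: rows (bmi_lo, bmi_hi, disutility)
    obesity_disutility_by_bmi: Sequence[tuple] = ()
    baseline_utility_age_slope: float = 0.0
    age_anchor: float = 40.0

    def baseline_at(self, age: np.ndarray | float) -> np.ndarray | float:
        u = self.baseline_utility - self.baseline_utility_age_slope \
            * (np.asarray(age, dtype=float) - self.age_anchor)
        return np.clip(u, 0.0, 1.0)

    def validate(self) -> None:
        if not (0 <= self.baseline_utility <= 1):
            raise ConfigError("baseline_utility: must lie in [0,1]")
        if self.baseline_utility_age_slope < 0:
            raise ConfigError("baseline_utility_age_slope: must be nonnegative")
        for cond, d in self.disutilities.items():
            if cond not in CONDITIONS:
                raise ConfigError(f"disutilities: unknown condition '{cond}'")
            if not (0 <= d <= 1):
                raise ConfigError(f"disutilities[{cond}]: must lie in [0,1]")

    def obesity_disutility(self, bmi: np.ndarray) -> np.ndarray:
        """Disutility for obese person-years as a function of BMI."""
        if not self.obesity_disutility_by_bmi:
            return np.full(np.shape(bmi), self.disutilities.get("obesity", 0.0))
        out = np.zeros(np.shape(bmi))
        for lo, hi, d in self.obesity_disutility_by_bmi:
            out = np.where((bmi >= lo) & (bmi < hi), d, out)
        return out

    def disutility_matrix(self, flags: np.ndarray, bmi: np.ndarray) -> np.ndarray:
        """(n, 6) per-condition disutility contributions of active conditions."""
        n = flags.shape[0]
        loss = np.zeros((n, N_COND))
        for k, cond in enumerate(CONDITIONS):
            if cond == "obesity":
                loss[:, k] = np.where(flags[:, k], self.obesity_disutility(bmi), 0.0)
            else:
                loss[:, k] = np.where(flags[:, k], self.disutilities.get(cond, 0.0), 0.0)
        return loss


def person_year_utility(flags: Mapping[str, bool], bmi: float,
                        utilities: UtilityTable,
                        age: float | None = None) -> float:
    """QALY weight of one alive person-year: baseline minus active disutilities.

    Floored at zero (a lived year never scores below death).  `age` engages
    the age-declining baseline; omitted, the anchor-age baseline applies.
    """
    utilities.validate()
    for cond in flags:
        if cond not in CONDITIONS:
            raise ConfigError(f"person_year_utility: unknown condition '{cond}'")
    fl = np.array([[bool(flags.get(c, False)) for c in CONDITIONS]])
    loss = utilities.disutility_matrix(fl, np.array([bmi])).sum()
    base = utilities.baseline_utility if age is None else float(utilities.baseline_at(age))
    return float(max(0.0, base - loss))


@dataclass
class CostTable:
    """Annual per-condition costs (Dec-2019 USD) and the premature-death cost.

    Health-care costs may differ between working age and post-retirement
    (care intensity for strokes, kidney disease etc. concentrates in old
    age); `annual_health_cost_postretirement` falls back to the working-age
    level where unset.
    """

    annual_health_cost: Mapping[str, float] = field(default_factory=dict)
    annual_productivity_cost: Mapping[str, float] = field(default_factory=dict)
    annual_health_cost_postretirement: Mapping[str, float] = field(default_factory=dict)
    death_productivity_cost: float = 0.0
    cpi_factor_to_dec2019: float = 1.0

    def health_cost_postretirement(self, cond: str) -> float:
        if cond in self.annual_health_cost_postretirement:
            return self.annual_health_cost_postretirement[cond]
        return self.annual_health_cost.get(cond, 0.0)

    def validate(self) -> None:
        for m, name in ((self.annual_health_cost, "annual_health_cost"),
                        (self.annual_productivity_cost, "annual_productivity_cost"),
                        (self.annual_health_cost_postretirement,
                         "annual_health_cost_postretirement")):
            for cond, v in m.items():
                if cond not in CONDITIONS:
                    raise ConfigError(f"{name}: unknown condition '{cond}'")
                if v < 0:
                    raise ConfigError(f"{name}[{cond}]: costs must be nonnegative")
        if self.death_productivity_cost < 0:
            raise ConfigError("death_productivity_cost: must be nonnegative")

    def inflated(self) -> "CostTable":
        """Apply the CPI factor once, returning a constant-dollar table."""
        f = self.cpi_factor_to_dec2019
        return CostTable(
            annual_health_cost={c: v * f for c, v in self.annual_health_cost.items()},
            annual_productivity_cost={c: v * f
                                      for c, v in self.annual_productivity_cost.items()},
            annual_health_cost_postretirement={
                c: v * f for c, v in self.annual_health_cost_postretirement.items()},
            death_productivity_cost=self.death_productivity_cost * f,
            cpi_factor_to_dec2019=1.0,
        )


@dataclass
class EconomicAssumptions:
    """Discounting, horizons, payer shares, and employment-plan dynamics."""

    discount_rate: float = 0.03
    employer_horizon: int = 10
    employer_cost_share: float = 0.80
    annual_attrition_rate: float = 0.05
    retirement_age: float = 65.0
    perspective: str = "employer"  # or "healthcare"

    def validate(self) -> None:
        if self.discount_rate < 0:
            raise ConfigError("discount_rate: must be nonnegative")
        for v, name in ((self.employer_cost_share, "employer_cost_share"),
                        (self.annual_attrition_rate, "annual_attrition_rate")):
            if not (0 <= v <= 1):
                raise ConfigError(f"{name}: must lie in [0,1]")
        if self.perspective not in ("employer", "healthcare"):
            raise ConfigError(f"perspective: unknown '{self.perspective}'")


def person_year_cost(flags: Mapping[str, bool], enrolled: bool, employed: bool,
                     age: float, costs: CostTable, econ: EconomicAssumptions,
                     alive: bool = True) -> dict[str, float]:
    """One person-year's cost by channel; dead person-years cost nothing."""
    costs.validate()
    if not alive:
        return {"health_employer": 0.0, "health_other": 0.0, "productivity": 0.0}
    employer_payer = enrolled and age < econ.retirement_age
    health = sum(costs.annual_health_cost.get(c, 0.0)
                 for c in CONDITIONS if flags.get(c, False))
    prod = sum(costs.annual_productivity_cost.get(c, 0.0)
               for c in CONDITIONS if flags.get(c, False)) if employed else 0.0
    share = econ.employer_cost_share if employer_payer else 0.0
    return {"health_employer": share * health,
            "health_other": (1.0 - share) * health,
            "productivity": prod}


class EconRecorder:
    """Accumulates discounted QALYs and costs per person and category.

    Snapshots its accumulators at the employer horizon so a single lifetime
    run yields both the 10-year (employer) and lifetime (health-care)
    perspectives.
    """

    def __init__(self, pop, utilities: UtilityTable, costs: CostTable,
                 econ: EconomicAssumptions):
        utilities.validate()
        costs.validate()
        econ.validate()
        self.utilities = utilities
        self.costs = costs.inflated()
        self.econ = econ
        n = len(pop)
        self.n = n
        self._baseline_ages = np.asarray(pop.col("age"), dtype=float).copy()
        z = lambda *shape: np.zeros(shape if shape else n)  # noqa: E731
        self.arrays = {
            "qaly_disc": z(), "qaly_undisc": z(), "py_disc": z(), "py_undisc": z(),
            "py_base_disc": z(), "py_base_undisc": z(),   # baseline-utility py
            "qaly_loss_disc": z(n, N_COND),          # per-condition disutility losses
            "qaly_loss_undisc": z(n, N_COND),
            "health_employer": z(n, N_COND), "health_other": z(n, N_COND),
            "productivity": z(n, N_COND),
            "death_cost": z(n, N_COND + 1),          # by cause; last = other
        }
        self.snapshots: dict[int, dict[str, np.ndarray]] = {}

    def record_year(self, rec: YearRecord, state: SimState) -> None:
        u = self.utilities
        c = self.costs
        econ = self.econ
        disc = discount_factor(rec.year, econ.discount_rate)
        survived = rec.alive_start & ~rec.died
        dying = rec.alive_start & rec.died
        # exposure time: full cycle if survived, half if died this cycle
        py = survived * 1.0 + dying * 0.5
        flags = np.where(survived[:, None], rec.flags_end, rec.flags_start)
        burden = rec.burden_mult if rec.burden_mult is not None else 1.0
        burden_u = rec.burden_util_mult if rec.burden_util_mult is not None else burden

        loss = u.disutility_matrix(flags, rec.bmi) * burden_u * py[:, None]
        raw = u.baseline_at(rec.age_start) * py
        total_loss = loss.sum(axis=1)
        over = total_loss > raw
        if np.any(over):  # floor at zero, attributing the cap proportionally
            scale = np.ones(self.n)
            scale[over] = raw[over] / total_loss[over]
            loss *= scale[:, None]
            total_loss = loss.sum(axis=1)
        qaly = raw - total_loss

        a = self.arrays
        a["qaly_disc"] += disc * qaly
        a["qaly_undisc"] += qaly
        a["py_disc"] += disc * py
        a["py_undisc"] += py
        a["py_base_disc"] += disc * raw
        a["py_base_undisc"] += raw
        a["qaly_loss_disc"] += disc * loss
        a["qaly_loss_undisc"] += loss

        hc_y = np.array([c.annual_health_cost.get(cond, 0.0) for cond in CONDITIONS])
        hc_o = np.array([c.health_cost_postretirement(cond) for cond in CONDITIONS])
        pc = np.array([c.annual_productivity_cost.get(cond, 0.0) for cond in CONDITIONS])
        hc = np.where((rec.age_start < econ.retirement_age)[:, None],
                      hc_y[None, :], hc_o[None, :])
        cost_h = flags * burden * hc * py[:, None]
        employer_payer = rec.enrolled_start & (rec.age_start < econ.retirement_age)
        share = np.where(employer_payer, econ.employer_cost_share, 0.0)
        a["health_employer"] += disc * cost_h * share[:, None]
        a["health_other"] += disc * cost_h * (1.0 - share[:, None])
        a["productivity"] += disc * flags * burden * pc[None, :] \
            * (rec.employed_start * py)[:, None]

        # premature-death productivity cost: condition-linked deaths only
        premature = dying & (rec.age_start < econ.retirement_age)
        if np.any(premature):
            for code in range(N_COND):
                m = premature & (rec.death_cause == code)
                a["death_cost"][m, code] += disc * c.death_productivity_cost

        if rec.year == econ.employer_horizon - 1:
            self.snapshots[econ.employer_horizon] = {k: v.copy()
                                                     for k, v in self.arrays.items()}

    def totals(self, horizon: str = "lifetime") -> dict[str, np.ndarray]:
        """Accumulated arrays for 'lifetime' or the employer horizon."""
        if horizon == "lifetime":
            return self.arrays
        key = self.econ.employer_horizon
        # if the run ended before the employer horizon, final arrays apply
        return self.snapshots.get(key, self.arrays)


def _arm_decomposition(recorder: EconRecorder, horizon: str, perspective: str,
                       scale: float, mask: np.ndarray | None = None) -> pd.Series:
    """Per-category QALYs and costs for one arm, scaled per 10,000 persons."""
    t = recorder.totals(horizon)
    m = mask if mask is not None else np.ones(recorder.n, dtype=bool)
    out: dict[str, float] = {}
    out["qalys_disc"] = t["qaly_disc"][m].sum() * scale
    out["qalys_undisc"] = t["qaly_undisc"][m].sum() * scale
    out["py_undisc"] = t["py_undisc"][m].sum() * scale
    out["qaly_base_disc"] = t["py_base_disc"][m].sum() * scale
    for k, cond in enumerate(CONDITIONS):
        out[f"qaly_loss_{cond}"] = t["qaly_loss_disc"][m, k].sum() * scale
    if perspective == "employer":
        per_cond = (t["health_employer"][m].sum(axis=0)
                    + t["productivity"][m].sum(axis=0)
                    + t["death_cost"][m, :N_COND].sum(axis=0)) * scale
        other = t["death_cost"][m, N_COND].sum() * scale
    else:  # healthcare: all payers' health costs, no productivity channels
        per_cond = (t["health_employer"][m].sum(axis=0)
                    + t["health_other"][m].sum(axis=0)) * scale
        other = 0.0
    for k, cond in enumerate(CONDITIONS):
        out[f"cost_{cond}"] = per_cond[k]
    out["cost_other_mortality"] = other
    out["cost_total"] = per_cond.sum() + other
    return pd.Series(out)


@dataclass
class ScenarioResult:
    """Mean and percentile-CI summary of paired Monte Carlo replicates."""

    perspective: str
    horizon: str
    table: pd.DataFrame                    # rows: categories + total
    per_replicate: pd.DataFrame            # replicate-level diffs and totals
    by_group: pd.DataFrame | None = None
    n_persons: int = 0
    n_replicates: int = 0

    def to_json_dict(self) -> dict:
        return {
            "perspective": self.perspective,
            "horizon": self.horizon,
            "n_persons": self.n_persons,
            "n_replicates": self.n_replicates,
            "table": self.table.reset_index().to_dict(orient="records"),
            "by_group": (self.by_group.reset_index().to_dict(orient="records")
                         if self.by_group is not None else None),
        }

    def to_exhibit_frame(self) -> pd.DataFrame:
        """Exhibit-style table: rows = outcomes + other mortality + total."""
        return self.table.copy()


def _replicate_diff_row(rep: ReplicateResult, horizon: str, perspective: str,
                        scale: float, mask=None) -> pd.Series:
    ctl = _arm_decomposition(rep.control.recorders[0], horizon, perspective, scale, mask)
    ban = _arm_decomposition(rep.ban.recorders[0], horizon, perspective, scale, mask)
    row: dict[str, float] = {"reduction": rep.reduction}
    # saved QALYs by category: reduced disutility per condition + life-years
    # from averted deaths valued at baseline utility
    for cond in CONDITIONS:
        row[f"qalys_saved_{cond}"] = ctl[f"qaly_loss_{cond}"] - ban[f"qaly_loss_{cond}"]
    row["qalys_saved_other_mortality"] = ban["qaly_base_disc"] - ctl["qaly_base_disc"]
    row["qalys_saved_total"] = ban["qalys_disc"] - ctl["qalys_disc"]
    for cat in CATEGORIES + ["total"]:
        row[f"cost_saved_{cat}"] = ctl[f"cost_{cat}"] - ban[f"cost_{cat}"]
    row["baseline_qalys_disc"] = ctl["qalys_disc"]
    row["baseline_qalys_undisc"] = ctl["qalys_undisc"]
    row["baseline_py_undisc"] = ctl["py_undisc"]
    row["baseline_cost_total"] = ctl["cost_total"]
    row["ban_cost_total"] = ban["cost_total"]
    row["ban_qalys_disc"] = ban["qalys_disc"]
    return pd.Series(row)


def aggregate_results(replicates: Sequence[ReplicateResult],
                      utilities: UtilityTable, costs: CostTable,
                      econ: EconomicAssumptions, horizon: str = "lifetime",
                      group_by: str | None = None,
                      scale_to: float = 10000.0) -> ScenarioResult:
    """Summarize paired replicates into an exhibit-style decomposition.

    Point estimates are replicate means; 95% CIs are the 2.5th/97.5th
    percentiles over replicates.  All quantities are normalized per
    `scale_to` persons (the conventional per-10,000 scale).  Category rows
    sum to totals exactly within each replicate before averaging.
    """
    if len(replicates) == 0:
        raise ValueError("aggregate_results: need at least one replicate")
    n = replicates[0].control.recorders[0].n
    for rep in replicates:
        if rep.control.recorders[0].n != rep.ban.recorders[0].n:
            raise ValueError("aggregate_results: mismatched arm ledgers")
    scale = scale_to / n
    perspective = econ.perspective
    rows = pd.DataFrame([_replicate_diff_row(r, horizon, perspective, scale)
                         for r in replicates])

    def mean_ci(col: str) -> tuple[float, float, float]:
        v = rows[col].to_numpy()
        return (float(v.mean()), float(np.percentile(v, 2.5)),
                float(np.percentile(v, 97.5)))

    table_rows = []
    for cat in CATEGORIES + ["total"]:
        q, ql, qh = mean_ci(f"qalys_saved_{cat}")
        c, cl, ch = mean_ci(f"cost_saved_{cat}")
        table_rows.append({"category": cat, "qalys_saved": q,
                           "qalys_saved_ci_lo": ql, "qalys_saved_ci_hi": qh,
                           "dollars_saved": c, "dollars_saved_ci_lo": cl,
                           "dollars_saved_ci_hi": ch})
    table = pd.DataFrame(table_rows).set_index("category")

    by_group = None
    if group_by is not None:
        col = {"race_ethnicity": "race", "occupational_class": "occupation"}.get(
            group_by, group_by)
        labels = getattr(replicates[0].control.state, col)
        grows = []
        for g in pd.unique(labels):
            mask = labels == g
            gscale = scale_to / mask.sum()
            gr = pd.DataFrame([
                _replicate_diff_row(r, horizon, perspective, gscale, mask)
                for r in replicates])
            grows.append({
                "group": g,
                "qalys_saved": float(gr["qalys_saved_total"].mean()),
                "qalys_saved_ci_lo": float(np.percentile(gr["qalys_saved_total"], 2.5)),
                "qalys_saved_ci_hi": float(np.percentile(gr["qalys_saved_total"], 97.5)),
                "dollars_saved": float(gr["cost_saved_total"].mean()),
                "dollars_saved_ci_lo": float(np.percentile(gr["cost_saved_total"], 2.5)),
                "dollars_saved_ci_hi": float(np.percentile(gr["cost_saved_total"], 97.5)),
            })
        by_group = pd.DataFrame(grows).set_index("group")

    return ScenarioResult(perspective=perspective, horizon=horizon, table=table,
                          per_replicate=rows, by_group=by_group,
                          n_persons=n, n_replicates=len(replicates))
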