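"""Annual-cycle microsimulation of chronic-disease incidence and mortality.

Each simulated employee advances through yearly cycles with a fixed event
order: (1) mortality (other-cause first, then cause-specific among prevalent
conditions), (2) disease incidence among survivors, (3) employment
transitions (attrition, retirement), (4) aging by one year.  Conditions are
absorbing by default.  Scenario relative risks multiply incidence
probabilities always and cause-specific mortality where configured.

Common random numbers: every cycle draws fixed-shape uniform blocks for all
persons (dead or alive) in a fixed order, so two scenario arms run from the
same seed consume identical streams and their difference isolates the
intervention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .intervention import EffectSizeTable, InterventionEffect, person_level_reductions
from .population import CONDITIONS, ConfigError, Population

AGE_CAP = 110.0
N_COND = len(CONDITIONS)

#: death-cause codes in the trajectory ledger
CAUSE_NONE = -1
CAUSE_OTHER = N_COND  # background / other-cause mortality (incl. age cap)

#: BMI assigned to a person who becomes obese during simulation (kg/m^2).
INCIDENT_OBESITY_BMI = 32.0


class RateTable:
    """Annual probabilities indexed by sex and age band.

    Bands must partition [16, 110); lookup outside the covered range is a
    configuration error naming the missing stratum.
    """

    def __init__(self, records: Sequence[Mapping]):
        # records: {sex: 'male'|'female'|'both', age_lo, age_hi, rate}
        self._edges: dict[str, np.ndarray] = {}
        self._values: dict[str, np.ndarray] = {}
        by_sex: dict[str, list] = {"male": [], "female": []}
        for row in records:
            sexes = ("male", "female") if row.get("sex", "both") == "both" else (row["sex"],)
            for s in sexes:
                if s not in by_sex:
                    raise ConfigError(f"rate table: unknown sex '{s}'")
                by_sex[s].append((float(row["age_lo"]), float(row["age_hi"]), float(row["rate"])))
        for s, rows in by_sex.items():
            rows.sort()
            if not rows:
                raise ConfigError(f"rate table: no rows for sex '{s}'")
            edges = [rows[0][0]] + [r[1] for r in rows]
            vals = [r[2] for r in rows]
            for (lo, hi, v), prev_hi in zip(rows[1:], edges[1:-1]):
                if abs(lo - prev_hi) > 1e-9:
                    raise ConfigError(
                        f"rate table: bands for sex '{s}' do not partition (gap at age {lo:g})")
            if rows[0][0] > 16.0 or rows[-1][1] < AGE_CAP:
                raise ConfigError(
                    f"rate table: bands for sex '{s}' must cover [16, {AGE_CAP:g})")
            vals_arr = np.asarray(vals, dtype=float)
            if np.any((vals_arr < 0) | (vals_arr > 1)):
                raise ConfigError("rate table: annual probabilities must lie in [0,1]")
            self._edges[s] = np.asarray(edges, dtype=float)
            self._values[s] = vals_arr

    @classmethod
    def constant(cls, rate: float) -> "RateTable":
        return cls([{"sex": "both", "age_lo": 16.0, "age_hi": AGE_CAP, "rate": rate}])

    @classmethod
    def from_hazard_records(cls, records: Sequence[Mapping]) -> "RateTable":
        """Build from continuous hazards via p = 1 - exp(-r)."""
        conv = [dict(r, rate=1.0 - np.exp(-float(r["rate"]))) for r in records]
        return cls(conv)

    @classmethod
    def from_age_function(cls, f: Callable[[np.ndarray], np.ndarray],
                         step: float = 1.0) -> "RateTable":
        """Tabulate an age->probability function on 1-year bands (sex-shared)."""
        los = np.arange(16.0, AGE_CAP, step)
        rates = np.clip(f(los + step / 2), 0.0, 1.0)
        return cls([{"sex": "both", "age_lo": lo, "age_hi": min(lo + step, AGE_CAP),
                     "rate": r} for lo, r in zip(los, rates)])

    def lookup(self, age: np.ndarray, is_male: np.ndarray) -> np.ndarray:
        age = np.minimum(np.asarray(age, dtype=float), AGE_CAP - 1e-9)
        out = np.empty(len(age), dtype=float)
        for s, mask in (("male", is_male), ("female", ~is_male)):
            if not np.any(mask):
                continue
            edges, vals = self._edges[s], self._values[s]
            a = age[mask]
            if np.any(a < edges[0] - 1e-9):
                raise ConfigError(
                    f"rate table: age {a.min():g} below covered range for sex '{s}'")
            idx = np.clip(np.searchsorted(edges, a, side="right") - 1, 0, len(vals) - 1)
            out[mask] = vals[idx]
        return out

    def scaled(self, factor: float) -> "RateTable":
        """Return a copy with all probabilities multiplied (clipped to [0,1])."""
        if factor <= 0:
            raise ConfigError("rate table scaling: factor must be positive")
        recs = [dict(r, rate=min(1.0, r["rate"] * factor)) for r in self.to_records("x")]
        return RateTable(recs)

    def to_records(self, name: str = "") -> list[dict]:
        rows = []
        for s in ("male", "female"):
            edges, vals = self._edges[s], self._values[s]
            for lo, hi, v in zip(edges[:-1], edges[1:], vals):
                rows.append({"outcome": name, "sex": s, "age_lo": lo, "age_hi": hi, "rate": v})
        return rows


@dataclass
class DiseaseModel:
    """One chronic-disease outcome's transition schedules."""

    name: str
    annual_incidence: RateTable
    case_fatality: RateTable = field(default_factory=lambda: RateTable.constant(0.0))
    remission_allowed: bool = False
    contributes_to_mortality: bool = False

    def validate(self) -> None:
        if self.name not in CONDITIONS:
            raise ConfigError(f"disease model: unknown outcome '{self.name}'")


@dataclass
class BackgroundMortality:
    """Annual probability of death from causes other than the six outcomes."""

    table: RateTable

    def lookup(self, age, is_male):
        return self.table.lookup(age, is_male)


@dataclass
class EmploymentModel:
    """Employer-plan dynamics: annual attrition and retirement age."""

    annual_attrition_rate: float = 0.05
    retirement_age: float = 65.0

    def validate(self) -> None:
        if not (0 <= self.annual_attrition_rate <= 1):
            raise ConfigError("annual_attrition_rate: must lie in [0,1]")


@dataclass
class Scenario:
    """Per-person relative risks applied during exposed person-years.

    `rr_incidence` / `rr_mortality` map outcome name to a scalar or length-n
    array; `rr_other_mortality` multiplies background mortality.  Exposure
    `while_employed` switches the RRs off once a person retires or leaves the
    employer (accrued disease states persist).
    """

    rr_incidence: Mapping[str, np.ndarray | float] = field(default_factory=dict)
    rr_mortality: Mapping[str, np.ndarray | float] = field(default_factory=dict)
    rr_burden: Mapping[str, np.ndarray | float] = field(default_factory=dict)
    rr_burden_utility: Mapping[str, np.ndarray | float] = field(default_factory=dict)
    rr_other_mortality: np.ndarray | float = 1.0
    exposure: str = "while_employed"  # or "always"
    reduction: float = 0.0            # population-mean oz/day (bookkeeping)

    @classmethod
    def null(cls) -> "Scenario":
        return cls()

    @classmethod
    def from_effect_table(cls, table: EffectSizeTable, reduction: float,
                          ssb_oz_per_day: np.ndarray,
                          exposure: str = "while_employed",
                          occupational_class: np.ndarray | None = None
                          ) -> "Scenario":
        """Build per-person RRs for a population-mean reduction.

        Individual reductions are capped at each person's baseline intake
        before the log-linear RR rescaling; optional subgroup multipliers
        scale the reduction by occupational class first.
        """
        table.validate()
        target = np.full(len(ssb_oz_per_day), float(reduction))
        if table.subgroup_multipliers and occupational_class is not None:
            for occ, mult in table.subgroup_multipliers.items():
                target[occupational_class == occ] *= mult
        per_person = person_level_reductions(target, ssb_oz_per_day)
        rr_inc = {c: table.rr_at(c, per_person, "incidence") for c in CONDITIONS}
        rr_mort = {c: table.rr_at(c, per_person, "mortality") for c in CONDITIONS}
        rr_burd = {c: table.rr_at(c, per_person, "burden") for c in CONDITIONS}
        rr_burd_u = {c: table.rr_at(c, per_person, "disutility_burden")
                     for c in CONDITIONS}
        rr_other = table.rr_at("other_mortality", per_person, "mortality")
        return cls(rr_incidence=rr_inc, rr_mortality=rr_mort, rr_burden=rr_burd,
                   rr_burden_utility=rr_burd_u, rr_other_mortality=rr_other,
                   exposure=exposure, reduction=reduction)


@dataclass
class AnnualEvent:
    """Events occurring to one person during one cycle."""

    person_id: int
    cycle_year: int
    incident_conditions: set
    died: bool
    cause: str | None
    aged_out_of_employment: bool
    retired: bool


class SimState:
    """Mutable column store for the population during simulation."""

    def __init__(self, pop: Population):
        df = pop.frame
        self.n = len(df)
        self.person_id = df.person_id.to_numpy()
        self.age = df.age.to_numpy(dtype=float).copy()
        self.is_male = (df.sex == "male").to_numpy()
        self.race = df.race_ethnicity.to_numpy()
        self.occupation = df.occupational_class.to_numpy()
        self.insured = df.insured.to_numpy(dtype=bool).copy()
        self.enrolled = df.enrolled_in_employer_plan.to_numpy(dtype=bool).copy()
        self.bmi = df.bmi.to_numpy(dtype=float).copy()
        self.ssb = df.ssb_oz_per_day.to_numpy(dtype=float).copy()
        self.flags = np.column_stack([df[c].to_numpy(dtype=bool) for c in CONDITIONS]).copy()
        self.alive = df.alive.to_numpy(dtype=bool).copy()
        self.exited = np.zeros(self.n, dtype=bool)  # left the employer (attrition)

    def employed(self, employment: EmploymentModel) -> np.ndarray:
        return self.alive & ~self.exited & (self.age < employment.retirement_age)

    def enrolled_in_plan(self, employment: EmploymentModel) -> np.ndarray:
        return self.enrolled & self.employed(employment)


@dataclass
class YearRecord:
    """Snapshot handed to recorders after each cycle (arrays over all persons)."""

    year: int
    age_start: np.ndarray
    alive_start: np.ndarray
    died: np.ndarray
    death_cause: np.ndarray          # int codes, CAUSE_NONE if none
    flags_start: np.ndarray          # (n, 6) at cycle start
    flags_end: np.ndarray            # (n, 6) after incidence
    bmi: np.ndarray
    employed_start: np.ndarray
    enrolled_start: np.ndarray
    incident: np.ndarray             # (n, 6) new conditions this cycle
    burden_mult: np.ndarray | None = None       # (n, 6) cost multipliers
    burden_util_mult: np.ndarray | None = None  # (n, 6) disutility multipliers


@dataclass
class CohortRun:
    """Output of a single-arm cohort simulation."""

    incident_cases: dict
    deaths_by_cause: dict
    person_years: int
    years_simulated: int
    ledger: pd.DataFrame | None
    state: SimState
    recorders: tuple


def _expand_rr(rr, n: int) -> np.ndarray:
    arr = np.asarray(rr, dtype=float)
    return np.broadcast_to(arr, (n,))


def advance_year(state: SimState, models: Mapping[str, DiseaseModel],
                 background: BackgroundMortality, scenario: Scenario,
                 employment: EmploymentModel, rng: np.random.Generator,
                 year: int) -> YearRecord:
    """Advance every person by one annual cycle (fixed draw order, CRN-safe)."""
    n = state.n
    # fixed-shape draw blocks, independent of who is alive
    u_bg = rng.random(n)
    u_cause = rng.random((n, N_COND))
    u_inc = rng.random((n, N_COND))
    u_attr = rng.random(n)

    alive_start = state.alive.copy()
    flags_start = state.flags.copy()
    age_start = state.age.copy()
    employed_start = state.employed(employment)
    enrolled_start = state.enrolled_in_plan(employment)
    exposed = employed_start if scenario.exposure == "while_employed" else alive_start

    missing = [c for c in CONDITIONS if c not in models]
    if missing:
        raise ConfigError(f"disease registry: missing models for {missing}")

    # --- mortality -------------------------------------------------------
    rr_other = np.where(exposed, _expand_rr(scenario.rr_other_mortality, n), 1.0)
    p_bg = np.clip(background.lookup(age_start, state.is_male) * rr_other, 0.0, 1.0)
    died = alive_start & ((u_bg < p_bg) | (age_start >= AGE_CAP - 1))  # age-cap rule
    cause = np.full(n, CAUSE_NONE, dtype=np.int8)
    cause[died] = CAUSE_OTHER
    for k, cond in enumerate(CONDITIONS):
        dm = models[cond]
        if not dm.contributes_to_mortality:
            continue
        rr_m = np.where(exposed, _expand_rr(scenario.rr_mortality.get(cond, 1.0), n), 1.0)
        p = np.clip(dm.case_fatality.lookup(age_start, state.is_male) * rr_m, 0.0, 1.0)
        hit = alive_start & ~died & flags_start[:, k] & (u_cause[:, k] < p)
        died |= hit
        cause[hit] = k

    survivors = alive_start & ~died

    # --- incidence among survivors ----------------------------------------
    incident = np.zeros((n, N_COND), dtype=bool)
    for k, cond in enumerate(CONDITIONS):
        dm = models[cond]
        rr_i = np.where(exposed, _expand_rr(scenario.rr_incidence.get(cond, 1.0), n), 1.0)
        p = np.clip(dm.annual_incidence.lookup(age_start, state.is_male) * rr_i, 0.0, 1.0)
        incident[:, k] = survivors & ~state.flags[:, k] & (u_inc[:, k] < p)
        state.flags[incident[:, k], k] = True

    k_ob = CONDITIONS.index("obesity")
    new_obese = incident[:, k_ob]
    if np.any(new_obese):
        state.bmi[new_obese] = np.maximum(state.bmi[new_obese], INCIDENT_OBESITY_BMI)

    # --- employment transitions -------------------------------------------
    attrit = survivors & ~state.exited & (age_start < employment.retirement_age) \
        & (u_attr < employment.annual_attrition_rate)
    state.exited |= attrit

    # --- burden multipliers (severity response of prevalent cases) --------
    def _burden_matrix(rr_map) -> np.ndarray:
        mat = np.ones((n, N_COND))
        for k, cond in enumerate(CONDITIONS):
            rr_b = rr_map.get(cond, 1.0)
            if np.ndim(rr_b) or rr_b != 1.0:
                mat[:, k] = np.where(exposed, _expand_rr(rr_b, n), 1.0)
        return mat

    burden = _burden_matrix(scenario.rr_burden) if scenario.rr_burden else \
        np.ones((n, N_COND))
    burden_util = _burden_matrix(scenario.rr_burden_utility) \
        if scenario.rr_burden_utility else burden

    # --- aging and vital status -------------------------------------------
    state.alive &= ~died
    state.age[state.alive] += 1.0

    return YearRecord(year=year, age_start=age_start, alive_start=alive_start,
                      died=died, death_cause=cause, flags_start=flags_start,
                      flags_end=state.flags.copy(), bmi=state.bmi.copy(),
                      employed_start=employed_start, enrolled_start=enrolled_start,
                      incident=incident, burden_mult=burden,
                      burden_util_mult=burden_util)


def step_year(person, models: Mapping[str, DiseaseModel],
              background: BackgroundMortality, scenario_rrs: Scenario,
              rng: np.random.Generator,
              employment: EmploymentModel | None = None,
              cycle_year: int = 0):
    """Advance a single person by one cycle; returns (PersonState, AnnualEvent).

    Thin wrapper over the vectorized :func:`advance_year` with n = 1.
    """
    employment = employment or EmploymentModel(annual_attrition_rate=0.0)
    if not person.alive:
        raise ValueError("step_year: person must be alive")
    df = pd.DataFrame([{
        "person_id": person.person_id, "age": person.age, "sex": person.sex,
        "race_ethnicity": person.race_ethnicity,
        "occupational_class": person.occupational_class,
        "insured": person.insured,
        "enrolled_in_employer_plan": person.enrolled_in_employer_plan,
        "bmi": person.bmi, "ssb_oz_per_day": person.ssb_oz_per_day,
        **person.condition_flags, "alive": person.alive,
    }])
    state = SimState(Population(df))
    rec = advance_year(state, models, background, scenario_rrs, employment, rng, cycle_year)
    from .population import PersonState
    updated = PersonState(
        person_id=person.person_id, age=float(state.age[0]), sex=person.sex,
        race_ethnicity=person.race_ethnicity,
        occupational_class=person.occupational_class, insured=person.insured,
        enrolled_in_employer_plan=bool(state.enrolled_in_plan(employment)[0]),
        bmi=float(state.bmi[0]), ssb_oz_per_day=person.ssb_oz_per_day,
        condition_flags={c: bool(state.flags[0, i]) for i, c in enumerate(CONDITIONS)},
        alive=bool(state.alive[0]),
    )
    cause = None
    if rec.died[0]:
        code = int(rec.death_cause[0])
        cause = CONDITIONS[code] if code < N_COND else "other"
    event = AnnualEvent(
        person_id=person.person_id, cycle_year=cycle_year,
        incident_conditions={c for i, c in enumerate(CONDITIONS) if rec.incident[0, i]},
        died=bool(rec.died[0]), cause=cause,
        aged_out_of_employment=bool(state.exited[0]),
        retired=bool(state.age[0] >= employment.retirement_age and state.alive[0]),
    )
    return updated, event


def run_cohort(pop: Population, models: Mapping[str, DiseaseModel],
               background: BackgroundMortality, scenario: Scenario,
               horizon: int | str, rng: np.random.Generator | int,
               employment: EmploymentModel | None = None,
               recorders: Sequence = (), collect_ledger: bool = False) -> CohortRun:
    """Simulate one arm over a fixed horizon (years) or "lifetime".

    Every person alive at a cycle start contributes one person-year row; the
    year of death is included.  Reproducible given the seed / generator.
    """
    if len(pop) == 0:
        raise ValueError("run_cohort: population is empty")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    employment = employment or EmploymentModel()
    employment.validate()
    state = SimState(pop)

    if horizon == "lifetime":
        n_years = int(np.ceil(AGE_CAP - state.age.min())) + 1
    else:
        n_years = int(horizon)
        if n_years < 1:
            raise ConfigError(f"horizon: must be >= 1 year or 'lifetime', got {horizon}")

    incident_cases = {c: 0 for c in CONDITIONS}
    deaths_by_cause = {c: 0 for c in CONDITIONS}
    deaths_by_cause["other"] = 0
    person_years = 0
    ledger_rows: list[pd.DataFrame] = []

    years_done = 0
    for year in range(n_years):
        if not np.any(state.alive):
            break
        rec = advance_year(state, models, background, scenario, employment, rng, year)
        years_done = year + 1
        person_years += int(rec.alive_start.sum())
        for k, cond in enumerate(CONDITIONS):
            incident_cases[cond] += int(rec.incident[:, k].sum())
            deaths_by_cause[cond] += int((rec.death_cause == k).sum())
        deaths_by_cause["other"] += int((rec.death_cause == CAUSE_OTHER).sum())
        for r in recorders:
            r.record_year(rec, state)
        if collect_ledger:
            m = rec.alive_start
            rows = pd.DataFrame({
                "person_id": state.person_id[m], "cycle_year": year,
                "age": rec.age_start[m],
                "employed": rec.employed_start[m], "enrolled": rec.enrolled_start[m],
                **{c: rec.flags_end[m, k] for k, c in enumerate(CONDITIONS)},
                "died": rec.died[m],
                "death_cause": [
                    (CONDITIONS[c] if 0 <= c < N_COND else ("other" if c == CAUSE_OTHER else ""))
                    for c in rec.death_cause[m]],
            })
            ledger_rows.append(rows)

    ledger = pd.concat(ledger_rows, ignore_index=True) if collect_ledger else None
    return CohortRun(incident_cases=incident_cases, deaths_by_cause=deaths_by_cause,
                     person_years=person_years, years_simulated=years_done,
                     ledger=ledger, state=state, recorders=tuple(recorders))


class EventWindowRecorder:
    """Counts incident cases and deaths by cause within a year window."""

    def __init__(self, window_years: int):
        self.window_years = window_years
        self.incident = np.zeros(N_COND)
        self.cause_deaths = np.zeros(N_COND)
        self.other_deaths = 0.0

    def record_year(self, rec: YearRecord, state: SimState) -> None:
        if rec.year >= self.window_years:
            return
        self.incident += rec.incident.sum(axis=0)
        for k in range(N_COND):
            self.cause_deaths[k] += int((rec.death_cause == k).sum())
        self.other_deaths += int((rec.death_cause == CAUSE_OTHER).sum())

    def events(self) -> np.ndarray:
        """Incident cases plus cause-specific deaths, per outcome."""
        return self.incident + self.cause_deaths


@dataclass
class ReplicateResult:
    """One Monte Carlo replicate: paired control/ban arms under CRN."""

    replicate: int
    reduction: float
    control: CohortRun
    ban: CohortRun
    param_seed: int


def run_paired_scenarios(pop, models: Mapping[str, DiseaseModel],
                         background: BackgroundMortality,
                         effect_table: EffectSizeTable,
                         effect: InterventionEffect,
                         horizon: int | str, n_replicates: int, seed: int,
                         employment: EmploymentModel | None = None,
                         recorder_factory: Callable | None = None,
                         collect_ledger: bool = False,
                         forced_reduction: float | None = None,
                         exposure: str = "while_employed") -> list[ReplicateResult]:
    """Run paired ban/control arms for each replicate with common random numbers.

    Per replicate: one reduction draw (parameter uncertainty), then both arms
    simulated from an identical event stream so that their difference
    isolates the intervention.  `pop` may be a fixed :class:`Population` or a
    callable `seed -> Population` (fresh sample per replicate).

    `forced_reduction` bypasses the effect distribution (used by the
    break-even search, which scans fixed reduction levels).
    """
    if n_replicates < 1:
        raise ConfigError("n_replicates: must be >= 1")
    results = []
    root = np.random.SeedSequence(seed)
    for rep in range(n_replicates):
        ss = np.random.SeedSequence(entropy=seed, spawn_key=(rep,))
        pop_seed, param_seed, event_seed = [
            int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)]
        population = pop(pop_seed) if callable(pop) else pop
        param_rng = np.random.default_rng(param_seed)
        if forced_reduction is not None:
            reduction = float(forced_reduction)
        else:
            reduction = float(effect.sample_reduction(param_rng))
        ssb = population.col("ssb_oz_per_day")
        ban = Scenario.from_effect_table(
            effect_table, reduction, ssb, exposure=exposure,
            occupational_class=population.col("occupational_class"))
        control = Scenario.null()
        runs = {}
        for arm, scen in (("control", control), ("ban", ban)):
            recs = recorder_factory(arm, population) if recorder_factory else ()
            runs[arm] = run_cohort(population, models, background, scen, horizon,
                                   np.random.default_rng(event_seed), employment,
                                   recorders=recs, collect_ledger=collect_ledger)
        results.append(ReplicateResult(replicate=rep, reduction=reduction,
                                       control=runs["control"], ban=runs["ban"],
                                       param_seed=param_seed))
    del root
    return results
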