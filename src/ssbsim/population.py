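"""Synthetic employee populations for workplace beverage-policy simulation.

The simulated population stands in for an NHANES-style sample of employed
adults: a joint distribution over age, sex, race/ethnicity, occupational
class, insurance coverage, BMI, habitual sugar-sweetened-beverage (SSB)
consumption, and prevalent chronic-disease states.  Sampling is
configuration-driven (no survey microdata): marginal fractions plus optional
age/sex-conditional prevalence tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

#: Canonical ordering of the six modeled chronic-disease outcomes.
CONDITIONS: tuple[str, ...] = ("obesity", "chd", "cva", "diabetes", "ckd", "dental")

#: Human-readable labels, used in reports.
CONDITION_LABELS: dict[str, str] = {
    "obesity": "Obesity",
    "chd": "Coronary heart disease",
    "cva": "Cerebrovascular accident",
    "diabetes": "Type 2 diabetes mellitus",
    "ckd": "Chronic kidney disease",
    "dental": "Dental disease",
}

SEXES: tuple[str, ...] = ("male", "female")

#: BMI threshold defining the obesity state (kg/m^2).
OBESITY_BMI_THRESHOLD = 30.0

AGE_MIN, AGE_MAX = 16.0, 100.0


class ConfigError(ValueError):
    """A configuration value violates its schema; the message names the field."""


def _check_fractions(name: str, fractions: Mapping[str, float]) -> None:
    vals = np.asarray(list(fractions.values()), dtype=float)
    if np.any(vals < 0):
        raise ConfigError(f"{name}: fractions must be nonnegative, got {dict(fractions)}")
    if abs(vals.sum() - 1.0) > 1e-9:
        raise ConfigError(f"{name}: fractions must sum to 1 (got {vals.sum():.12f})")


@dataclass
class AgeBands:
    """Piecewise-uniform age distribution over [16, 100)."""

    edges: Sequence[float]          # increasing band edges, length m+1
    weights: Sequence[float]        # band probabilities, length m

    def validate(self) -> None:
        edges = np.asarray(self.edges, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        if edges.ndim != 1 or len(edges) != len(w) + 1:
            raise ConfigError("age_distribution: edges must have one more entry than weights")
        if np.any(np.diff(edges) <= 0):
            raise ConfigError("age_distribution: edges must be strictly increasing")
        if edges[0] < AGE_MIN or edges[-1] > AGE_MAX:
            raise ConfigError(
                f"age_distribution: support must lie within [{AGE_MIN:g}, {AGE_MAX:g}]"
            )
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ConfigError("age_distribution: weights must be nonnegative and sum to 1")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        edges = np.asarray(self.edges, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        band = rng.choice(len(w), size=n, p=w / w.sum())
        u = rng.random(n)
        return edges[band] + u * (edges[band + 1] - edges[band])

    @property
    def mean(self) -> float:
        edges = np.asarray(self.edges, dtype=float)
        mid = 0.5 * (edges[:-1] + edges[1:])
        w = np.asarray(self.weights, dtype=float)
        return float(mid @ (w / w.sum()))

    def density_by_year(self) -> pd.Series:
        """Probability mass for each integer age (used by cohort expectation)."""
        edges = np.asarray(self.edges, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        ages = np.arange(int(np.floor(edges[0])), int(np.ceil(edges[-1])))
        mass = np.zeros(len(ages), dtype=float)
        for (lo, hi, wk) in zip(edges[:-1], edges[1:], w):
            density = wk / (hi - lo)
            overlap = np.clip(np.minimum(ages + 1, hi) - np.maximum(ages, lo), 0, None)
            mass += density * overlap
        return pd.Series(mass, index=ages)


@dataclass
class TruncLognormBMI:
    """Lognormal BMI truncated to [lo, hi] kg/m^2."""

    mu: float = 3.28        # log-scale location
    sigma: float = 0.18     # log-scale spread
    lo: float = 15.0
    hi: float = 60.0

    def validate(self) -> None:
        if self.sigma <= 0:
            raise ConfigError("bmi_distribution: sigma must be positive")
        if not (0 < self.lo < self.hi):
            raise ConfigError("bmi_distribution: support must be positive with lo < hi")

    def _dist(self):
        a = (np.log(self.lo) - self.mu) / self.sigma
        b = (np.log(self.hi) - self.mu) / self.sigma
        return stats.truncnorm(a, b, loc=self.mu, scale=self.sigma)

    def prob_obese(self) -> float:
        return float(self._dist().sf(np.log(OBESITY_BMI_THRESHOLD)))

    def sample_conditional(self, obese: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Sample BMI consistent with each person's obesity flag.

        Inverse-CDF sampling restricted to the region above/below the 30 kg/m^2
        threshold keeps the flag <-> BMI invariant exact.
        """
        d = self._dist()
        p_thr = d.cdf(np.log(OBESITY_BMI_THRESHOLD))
        u = rng.random(len(obese))
        q = np.where(obese, p_thr + u * (1 - p_thr), u * p_thr)
        return np.exp(d.ppf(np.clip(q, 1e-12, 1 - 1e-12)))

    def calibrated_to_obesity(self, prevalence: float) -> "TruncLognormBMI":
        """Return a copy with `mu` adjusted so P(BMI >= 30) = prevalence."""
        if not (0 < prevalence < 1):
            raise ConfigError("bmi_distribution: obesity prevalence must be in (0,1)")

        def f(mu: float) -> float:
            return TruncLognormBMI(mu, self.sigma, self.lo, self.hi).prob_obese() - prevalence

        mu = optimize.brentq(f, np.log(self.lo) + 0.05, np.log(self.hi) - 0.05)
        return TruncLognormBMI(mu, self.sigma, self.lo, self.hi)


@dataclass
class GammaSSB:
    """Gamma-distributed daily SSB consumption with optional zero inflation."""

    mean_oz_per_day: float = 11.7
    shape: float = 1.2
    zero_fraction: float = 0.0

    def validate(self) -> None:
        if self.mean_oz_per_day < 0:
            raise ConfigError("ssb_consumption_distribution: mean must be nonnegative")
        if self.shape <= 0:
            raise ConfigError("ssb_consumption_distribution: shape must be positive")
        if not (0 <= self.zero_fraction < 1):
            raise ConfigError("ssb_consumption_distribution: zero_fraction must be in [0,1)")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.mean_oz_per_day == 0:
            return np.zeros(n)
        positive_mean = self.mean_oz_per_day / (1 - self.zero_fraction)
        scale = positive_mean / self.shape
        x = rng.gamma(self.shape, scale, size=n)
        if self.zero_fraction > 0:
            x[rng.random(n) < self.zero_fraction] = 0.0
        return x

    def quantile_grid(self, m: int = 4096) -> np.ndarray:
        """Deterministic quantile representation of the distribution."""
        if self.mean_oz_per_day == 0:
            return np.zeros(m)
        positive_mean = self.mean_oz_per_day / (1 - self.zero_fraction)
        scale = positive_mean / self.shape
        q = (np.arange(m) + 0.5) / m
        x = stats.gamma.ppf(q, self.shape, scale=scale)
        n_zero = int(round(self.zero_fraction * m))
        if n_zero:
            x = stats.gamma.ppf((np.arange(m - n_zero) + 0.5) / (m - n_zero),
                                self.shape, scale=scale)
            x = np.concatenate([np.zeros(n_zero), x])
        return x


@dataclass
class DemographicsConfig:
    """Schema for the synthetic population generator (schema_version 1)."""

    age_distribution: AgeBands
    sex_fractions: Mapping[str, float]
    race_ethnicity_fractions: Mapping[str, float]
    occupational_class_fractions: Mapping[str, float]
    insurance_coverage_rate: float
    baseline_prevalence_by_condition: Mapping[str, object]
    bmi_distribution: TruncLognormBMI = field(default_factory=TruncLognormBMI)
    ssb_consumption_distribution: GammaSSB = field(default_factory=GammaSSB)
    # optional consumption shift by occupational class (multiplier on the
    # sampled intake; classes not listed default to 1.0)
    ssb_multiplier_by_occupation: Mapping[str, float] = field(default_factory=dict)
    schema_version: int = 1

    def validate(self) -> None:
        self.age_distribution.validate()
        _check_fractions("sex_fractions", self.sex_fractions)
        _check_fractions("race_ethnicity_fractions", self.race_ethnicity_fractions)
        _check_fractions("occupational_class_fractions", self.occupational_class_fractions)
        if not (0 <= self.insurance_coverage_rate <= 1):
            raise ConfigError("insurance_coverage_rate: must lie in [0,1]")
        for cond in CONDITIONS:
            if cond not in self.baseline_prevalence_by_condition:
                raise ConfigError(f"baseline_prevalence_by_condition: missing '{cond}'")
        for cond, spec in self.baseline_prevalence_by_condition.items():
            if cond not in CONDITIONS:
                raise ConfigError(f"baseline_prevalence_by_condition: unknown condition '{cond}'")
            for p in _prevalence_values(spec):
                if not (0 <= p <= 1):
                    raise ConfigError(
                        f"baseline_prevalence_by_condition[{cond}]: prevalence {p} outside [0,1]"
                    )
        self.bmi_distribution.validate()
        self.ssb_consumption_distribution.validate()
        for occ, mult in self.ssb_multiplier_by_occupation.items():
            if occ not in self.occupational_class_fractions:
                raise ConfigError(
                    f"ssb_multiplier_by_occupation: unknown class '{occ}'")
            if mult <= 0:
                raise ConfigError(
                    f"ssb_multiplier_by_occupation[{occ}]: must be positive")

    def prevalence_for(self, cond: str, age: np.ndarray, sex_is_male: np.ndarray) -> np.ndarray:
        """Per-person baseline prevalence, honoring conditional tables if given."""
        spec = self.baseline_prevalence_by_condition[cond]
        if np.isscalar(spec) or isinstance(spec, float) or isinstance(spec, int):
            return np.full(len(age), float(spec))
        # conditional table: list of {sex, age_lo, age_hi, prevalence}
        p = np.full(len(age), np.nan)
        for row in spec:
            mask = (age >= row["age_lo"]) & (age < row["age_hi"])
            if row.get("sex") in ("male", "female"):
                mask &= sex_is_male == (row["sex"] == "male")
            p[mask] = row["prevalence"]
        if np.isnan(p).any():
            raise ConfigError(
                f"baseline_prevalence_by_condition[{cond}]: conditional table leaves "
                "some (age, sex) strata uncovered"
            )
        return p


def _prevalence_values(spec) -> list[float]:
    if np.isscalar(spec):
        return [float(spec)]
    return [float(row["prevalence"]) for row in spec]


#: Fixed column order of the population CSV export.
POPULATION_COLUMNS = (
    ["person_id", "age", "sex", "race_ethnicity", "occupational_class",
     "insured", "enrolled_in_employer_plan", "bmi", "ssb_oz_per_day"]
    + list(CONDITIONS)
    + ["alive"]
)


@dataclass
class PersonState:
    """A single simulated employee (a row view of :class:`Population`)."""

    person_id: int
    age: float
    sex: str
    race_ethnicity: str
    occupational_class: str
    insured: bool
    enrolled_in_employer_plan: bool
    bmi: float
    ssb_oz_per_day: float
    condition_flags: dict[str, bool]
    alive: bool = True


class Population:
    """Vectorized container of :class:`PersonState` records.

    Internally column-oriented numpy arrays; iterate or index to get
    per-person :class:`PersonState` views.
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in POPULATION_COLUMNS if c not in df.columns]
        if missing:
            raise ConfigError(f"population table: missing columns {missing}")
        self._df = df.reset_index(drop=True)

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._df)

    def __getitem__(self, i: int) -> PersonState:
        row = self._df.iloc[i]
        return PersonState(
            person_id=int(row.person_id),
            age=float(row.age),
            sex=str(row.sex),
            race_ethnicity=str(row.race_ethnicity),
            occupational_class=str(row.occupational_class),
            insured=bool(row.insured),
            enrolled_in_employer_plan=bool(row.enrolled_in_employer_plan),
            bmi=float(row.bmi),
            ssb_oz_per_day=float(row.ssb_oz_per_day),
            condition_flags={c: bool(row[c]) for c in CONDITIONS},
            alive=bool(row.alive),
        )

    def __iter__(self):
        for i in range(len(self)):
            yield self[i]

    # -- column access ------------------------------------------------------
    def col(self, name: str) -> np.ndarray:
        return self._df[name].to_numpy()

    @property
    def frame(self) -> pd.DataFrame:
        return self._df

    def to_dataframe(self) -> pd.DataFrame:
        return self._df.copy()

    def to_csv(self, path) -> None:
        self._df.to_csv(path, index=False, columns=POPULATION_COLUMNS)

    @classmethod
    def from_csv(cls, path) -> "Population":
        return cls(pd.read_csv(path))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "Population":
        return cls(df.copy())


def generate_population(n: int, config: DemographicsConfig, seed: int) -> Population:
    """Sample `n` employees from the configured joint distribution.

    Conditions are sampled conditionally on age and sex where conditional
    prevalence tables are supplied (otherwise from the marginal prevalence);
    BMI is sampled conditionally on the obesity flag so that the
    flag <-> BMI >= 30 invariant holds exactly.  Deterministic given `seed`.
    """
    if n < 1:
        raise ConfigError(f"n: population size must be >= 1, got {n}")
    config.validate()
    rng = np.random.default_rng(seed)

    age = config.age_distribution.sample(n, rng)
    sex_names = list(config.sex_fractions)
    sex = np.array(sex_names)[rng.choice(len(sex_names), size=n,
                                         p=np.asarray(list(config.sex_fractions.values())))]
    race_names = list(config.race_ethnicity_fractions)
    race = np.array(race_names)[rng.choice(
        len(race_names), size=n, p=np.asarray(list(config.race_ethnicity_fractions.values())))]
    occ_names = list(config.occupational_class_fractions)
    occ = np.array(occ_names)[rng.choice(
        len(occ_names), size=n, p=np.asarray(list(config.occupational_class_fractions.values())))]
    insured = rng.random(n) < config.insurance_coverage_rate
    is_male = sex == "male"

    flags = {}
    for cond in CONDITIONS:
        p = config.prevalence_for(cond, age, is_male)
        flags[cond] = rng.random(n) < p

    bmi = config.bmi_distribution.sample_conditional(flags["obesity"], rng)
    ssb = config.ssb_consumption_distribution.sample(n, rng)
    if config.ssb_multiplier_by_occupation:
        for occ_name, mult in config.ssb_multiplier_by_occupation.items():
            ssb[occ == occ_name] *= mult

    df = pd.DataFrame({
        "person_id": np.arange(n, dtype=np.int64),
        "age": age,
        "sex": sex,
        "race_ethnicity": race,
        "occupational_class": occ,
        "insured": insured,
        "enrolled_in_employer_plan": insured,
        "bmi": bmi,
        "ssb_oz_per_day": ssb,
        **{c: flags[c] for c in CONDITIONS},
        "alive": np.ones(n, dtype=bool),
    })
    return Population(df)


def summarize_population(pop: Population) -> pd.Series:
    """Marginal summary: age mean/IQR, subgroup fractions, prevalences, SSB mean."""
    if len(pop) == 0:
        raise ValueError("summarize_population: population is empty")
    df = pop.frame
    out: dict[str, float] = {
        "n": float(len(df)),
        "age_mean": float(df.age.mean()),
        "age_q25": float(df.age.quantile(0.25)),
        "age_q75": float(df.age.quantile(0.75)),
        "ssb_oz_per_day_mean": float(df.ssb_oz_per_day.mean()),
        "bmi_mean": float(df.bmi.mean()),
        "insured_fraction": float(df.insured.mean()),
    }
    for s in SEXES:
        out[f"sex_{s}"] = float((df.sex == s).mean())
    for name, frac in df.race_ethnicity.value_counts(normalize=True).items():
        out[f"race_{name}"] = float(frac)
    for name, frac in df.occupational_class.value_counts(normalize=True).items():
        out[f"occupation_{name}"] = float(frac)
    for cond in CONDITIONS:
        out[f"prevalence_{cond}"] = float(df[cond].mean())
    return pd.Series(out)
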