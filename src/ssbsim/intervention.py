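"""Sales-ban effect: consumption-reduction distribution and relative-risk scaling.

The ban's effectiveness is summarized as a mean daily reduction in SSB
consumption (ounces/person/day) with a 95% CI, sampled per Monte Carlo
replicate as parameter uncertainty.  Per-outcome relative risks are
standardized to a reference reduction (1.5 oz/day) and rescaled to other
doses log-linearly, the conventional multiplicative dose-response form for
relative risks (keeps RR positive, identity at zero dose).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import stats

from .population import CONDITIONS, ConfigError

#: z-quantile used to convert a 95% CI half-width into a normal sigma.
_Z95 = 1.96

#: Key for the direct effect on mortality from causes other than the six outcomes.
OTHER_MORTALITY = "other_mortality"


@dataclass
class InterventionEffect:
    """Distribution of the ban-attributable mean SSB reduction (oz/person/day)."""

    mean_reduction: float = 1.5
    ci_lower: float = 0.7
    ci_upper: float = 2.4
    sampling_distribution: str = "truncated_normal"  # truncated at 0

    def validate(self) -> None:
        if self.mean_reduction < 0:
            raise ConfigError("mean_reduction: must be nonnegative")
        if not (self.ci_lower <= self.mean_reduction <= self.ci_upper):
            raise ConfigError("InterventionEffect: ci_lower <= mean_reduction <= ci_upper required")
        if self.sampling_distribution not in ("truncated_normal", "normal"):
            raise ConfigError(
                f"sampling_distribution: unknown '{self.sampling_distribution}'")

    @property
    def sigma(self) -> float:
        return (self.ci_upper - self.ci_lower) / (2 * _Z95)

    def sample_reduction(self, rng: np.random.Generator, size=None) -> float | np.ndarray:
        """Draw nonnegative reduction(s); degenerate CI returns the mean exactly."""
        self.validate()
        if self.sigma == 0:
            return self.mean_reduction if size is None else np.full(size, self.mean_reduction)
        if self.sampling_distribution == "truncated_normal":
            a = (0.0 - self.mean_reduction) / self.sigma
            draw = stats.truncnorm.rvs(a, np.inf, loc=self.mean_reduction,
                                       scale=self.sigma, size=size, random_state=rng)
        else:
            draw = np.maximum(0.0, rng.normal(self.mean_reduction, self.sigma, size=size))
        return float(draw) if size is None else draw


def sample_reduction(effect: InterventionEffect, rng: np.random.Generator,
                     size=None) -> float | np.ndarray:
    """Functional alias for :meth:`InterventionEffect.sample_reduction`."""
    return effect.sample_reduction(rng, size=size)


def scale_relative_risk(rr_ref: float | np.ndarray, reduction: float | np.ndarray,
                        reference: float = 1.5) -> float | np.ndarray:
    """Rescale an RR standardized at `reference` oz/day to another reduction.

    Log-linear in dose: rr(reduction) = exp((reduction/reference) * ln rr_ref),
    so rr(0) = 1 and rr(reference) = rr_ref.
    """
    rr_ref = np.asarray(rr_ref, dtype=float)
    if np.any(rr_ref <= 0):
        raise ConfigError("rr_ref: relative risk must be positive")
    if reference <= 0:
        raise ConfigError("reference: reference reduction must be positive")
    red = np.asarray(reduction, dtype=float)
    if np.any(red < 0):
        raise ConfigError("reduction: must be nonnegative")
    out = np.exp((red / reference) * np.log(rr_ref))
    return float(out) if out.ndim == 0 else out


@dataclass
class OutcomeEffect:
    """One outcome's RR at the reference reduction and the channels it acts on.

    Channels: `incidence` (new cases), `mortality` (cause-specific deaths
    among prevalent cases), and `burden` (the annual cost and disutility of a
    prevalent case scale with exposure — a severity/management-intensity
    dose response).
    """

    rr_at_reference: float
    applies_to: tuple[str, ...] = ("incidence", "mortality")
    # the burden channel may respond more weakly than event risk, and cost
    # and quality-of-life burden may differ in responsiveness; None = fall
    # back (disutility -> cost burden -> event RR)
    rr_burden_at_reference: float | None = None
    rr_disutility_at_reference: float | None = None

    def validate(self, name: str) -> None:
        if self.rr_at_reference <= 0:
            raise ConfigError(f"effect_sizes[{name}].rr_at_reference: must be positive")
        for attr in ("rr_burden_at_reference", "rr_disutility_at_reference"):
            v = getattr(self, attr)
            if v is not None and v <= 0:
                raise ConfigError(f"effect_sizes[{name}].{attr}: must be positive")
        for ch in self.applies_to:
            if ch not in ("incidence", "mortality", "burden"):
                raise ConfigError(f"effect_sizes[{name}].applies_to: unknown channel '{ch}'")


@dataclass
class EffectSizeTable:
    """Per-outcome RRs at the reference reduction, plus the other-cause-mortality RR.

    `subgroup_multipliers` optionally scales the consumption reduction by
    occupational class (surveys find larger decreases among blue-collar
    workers); default off (all 1.0).
    """

    effects: Mapping[str, OutcomeEffect] = field(default_factory=dict)
    reference_reduction: float = 1.5
    subgroup_multipliers: Mapping[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        if self.reference_reduction <= 0:
            raise ConfigError("reference_reduction: must be positive")
        for occ, mult in self.subgroup_multipliers.items():
            if mult <= 0:
                raise ConfigError(f"subgroup_multipliers[{occ}]: must be positive")
        for name, eff in self.effects.items():
            if name not in CONDITIONS and name != OTHER_MORTALITY:
                raise ConfigError(f"effect_sizes: unknown outcome '{name}'")
            eff.validate(name)

    def rr_at(self, name: str, reduction: float | np.ndarray,
              channel: str = "incidence") -> float | np.ndarray:
        """RR for `name` at a given reduction; 1.0 where the channel is off."""
        eff = self.effects.get(name)
        base_channel = "burden" if channel == "disutility_burden" else channel
        if eff is None or base_channel not in eff.applies_to:
            return np.ones_like(np.asarray(reduction, dtype=float)) \
                if np.ndim(reduction) else 1.0
        rr = eff.rr_at_reference
        if channel == "burden" and eff.rr_burden_at_reference is not None:
            rr = eff.rr_burden_at_reference
        elif channel == "disutility_burden":
            if eff.rr_disutility_at_reference is not None:
                rr = eff.rr_disutility_at_reference
            elif eff.rr_burden_at_reference is not None:
                rr = eff.rr_burden_at_reference
        return scale_relative_risk(rr, reduction, self.reference_reduction)


def person_level_reductions(population_reduction: float,
                            ssb_oz_per_day: np.ndarray) -> np.ndarray:
    """Apply a population-mean reduction per person, capped at baseline intake.

    The sampled reduction is a population-level parameter; an individual
    cannot reduce below zero consumption, so each person's realized reduction
    is min(reduction, baseline intake).
    """
    return np.minimum(population_reduction, np.maximum(ssb_oz_per_day, 0.0))
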