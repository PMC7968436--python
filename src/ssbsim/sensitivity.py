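"""Sensitivity analyses: uncompensated sales losses, ICER, break-even search.

In the base case, lost SSB revenue is fully offset by compensatory sales of
other beverages (offset fraction 1.0, loss = 0).  The pessimistic scenario
sets the offset to zero and charges the employer the discounted revenue lost
on at-work SSB purchases.  The break-even analysis finds the consumption
reduction at which discounted savings (health care + productivity) equal the
discounted sales loss, by bisection on common-random-number replicate means.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .economics import EconomicAssumptions, discount_factor
from .population import ConfigError, Population


@dataclass
class SalesAssumptions:
    """Workplace SSB revenue parameters."""

    price_per_oz: float = 0.10              # USD per ounce, at-work retail
    employer_profit_fraction: float = 0.50  # share of revenue accruing to employer
    work_fraction_of_consumption: float = 0.11  # share of daily ounces bought at work
    workdays_per_year: float = 250.0
    compensatory_offset_fraction: float = 1.0   # base case: fully offset
    price_uncertainty_cv: float = 0.25      # replicate-level lognormal CV on revenue

    def validate(self) -> None:
        for v, name in ((self.employer_profit_fraction, "employer_profit_fraction"),
                        (self.work_fraction_of_consumption, "work_fraction_of_consumption"),
                        (self.compensatory_offset_fraction, "compensatory_offset_fraction")):
            if not (0 <= v <= 1):
                raise ConfigError(f"{name}: must lie in [0,1]")
        if self.price_per_oz < 0:
            raise ConfigError("price_per_oz: must be nonnegative")
        if self.workdays_per_year <= 0 or self.workdays_per_year > 366:
            raise ConfigError("workdays_per_year: must lie in (0, 366]")
        if self.price_uncertainty_cv < 0:
            raise ConfigError("price_uncertainty_cv: must be nonnegative")


def compute_sales_loss(pop: Population, reduction: float, sales: SalesAssumptions,
                       econ: EconomicAssumptions, scale_to: float = 10000.0) -> float:
    """Discounted uncompensated SSB revenue loss, USD per `scale_to` persons.

    Annual loss per person = min(reduction, at-work ounces) x price x employer
    profit share x workdays x (1 - offset), accrued while employed (expected
    attrition decay, until retirement age), discounted over the employer
    horizon.  Nondecreasing and piecewise-linear in `reduction`, saturating
    at each person's at-work consumption.
    """
    sales.validate()
    econ.validate()
    if reduction < 0:
        raise ConfigError("reduction: must be nonnegative")
    atwork = sales.work_fraction_of_consumption * pop.col("ssb_oz_per_day")
    oz_per_day = np.minimum(reduction, atwork)
    annual = (oz_per_day * sales.price_per_oz * sales.employer_profit_fraction
              * sales.workdays_per_year * (1.0 - sales.compensatory_offset_fraction))
    age = pop.col("age")
    total = 0.0
    for t in range(econ.employer_horizon):
        employed = (age + t) < econ.retirement_age
        weight = (1.0 - econ.annual_attrition_rate) ** t
        total += discount_factor(t, econ.discount_rate) * weight * float(annual[employed].sum())
    return total * scale_to / len(pop)


def replicate_sales_losses(pop: Population, reductions: Sequence[float],
                           sales: SalesAssumptions, econ: EconomicAssumptions,
                           param_seeds: Sequence[int] | None = None,
                           scale_to: float = 10000.0) -> np.ndarray:
    """Per-replicate sales losses with price-parameter uncertainty.

    Each replicate's loss evaluates the loss curve at that replicate's
    reduction draw and multiplies by a lognormal revenue-parameter factor
    (mean 1, CV `price_uncertainty_cv`) derived from the replicate seed.
    """
    losses = np.array([compute_sales_loss(pop, float(r), sales, econ, scale_to)
                       for r in reductions])
    if sales.price_uncertainty_cv > 0 and param_seeds is not None:
        cv = sales.price_uncertainty_cv
        sigma = np.sqrt(np.log1p(cv ** 2))
        mults = np.array([
            np.exp(np.random.default_rng(np.random.SeedSequence(
                entropy=int(s), spawn_key=(1,))).normal(-sigma ** 2 / 2, sigma))
            for s in param_seeds])
        losses = losses * mults
    return losses


class UndefinedICERError(ZeroDivisionError):
    """Raised when the QALY difference is zero, leaving the ICER undefined."""


def icer(delta_cost: float, delta_qalys: float) -> float:
    """Incremental cost-effectiveness ratio, USD per QALY.

    Sign convention: `delta_cost` is the net cost of the intervention
    (negative = net saving, i.e. the intervention dominates), `delta_qalys`
    the QALYs it gains.  Scale-invariant: icer(a*c, a*q) = icer(c, q).
    """
    if delta_qalys == 0:
        raise UndefinedICERError("icer: QALY difference is zero")
    return delta_cost / delta_qalys


def icer_with_ci(delta_costs: Sequence[float],
                 delta_qalys: Sequence[float]) -> dict[str, float]:
    """ICER of replicate means, with a percentile CI over per-replicate ICERs."""
    dc = np.asarray(delta_costs, dtype=float)
    dq = np.asarray(delta_qalys, dtype=float)
    point = icer(float(dc.mean()), float(dq.mean()))
    ok = dq != 0
    per_rep = dc[ok] / dq[ok]
    return {"icer": point,
            "ci_lo": float(np.percentile(per_rep, 2.5)),
            "ci_hi": float(np.percentile(per_rep, 97.5))}


@dataclass
class BreakEvenResult:
    """Root of discounted savings = discounted sales loss."""

    breakeven_reduction: float              # oz/person/day
    lost_sales_at_breakeven: float          # USD per 10,000 over employer horizon
    savings_at_breakeven: float
    ci: tuple[float, float]                 # percentile CI of per-replicate roots
    tolerance_usd: float
    converged: bool
    curve: pd.DataFrame = field(default_factory=pd.DataFrame, repr=False)

    def to_json_dict(self) -> dict:
        return {"breakeven_reduction_oz_per_day": self.breakeven_reduction,
                "lost_sales_at_breakeven": self.lost_sales_at_breakeven,
                "savings_at_breakeven": self.savings_at_breakeven,
                "ci_lo": self.ci[0], "ci_hi": self.ci[1],
                "tolerance_usd": self.tolerance_usd, "converged": self.converged}


class BracketingError(ValueError):
    """The savings-loss difference does not change sign over the search bounds."""


def find_breakeven_reduction(savings_fn: Callable[[float], np.ndarray],
                             loss_fn: Callable[[float], np.ndarray],
                             lo: float = 0.05, hi: float = 8.0,
                             tolerance_usd: float = 100.0,
                             max_iter: int = 60) -> BreakEvenResult:
    """Bisection for the reduction where mean savings equal mean sales loss.

    `savings_fn(r)` / `loss_fn(r)` return per-replicate discounted USD per
    10,000 at a forced reduction `r` under fixed common-random-number seeds,
    so the mean curves are deterministic and (for monotone-difference
    configurations) cross at most once.  Per-replicate roots, interpolated
    from the evaluated grid, give the CI.
    """
    evals: dict[float, tuple[np.ndarray, np.ndarray]] = {}

    def g(r: float) -> float:
        if r not in evals:
            evals[r] = (np.asarray(savings_fn(r), dtype=float),
                        np.asarray(loss_fn(r), dtype=float))
        s, l = evals[r]
        return float(s.mean() - l.mean())

    g_lo, g_hi = g(lo), g(hi)
    if g_hi < 0:
        raise BracketingError(
            f"break-even root not bracketed: savings-loss is {g_lo:,.0f} at "
            f"{lo:g} oz/day and {g_hi:,.0f} at {hi:g} oz/day (both negative "
            "at the upper bound; savings never overtake losses)")
    if g_lo > 0:
        # savings exceed losses everywhere in the bracket: degenerate root at lo
        s, l = evals[lo]
        return BreakEvenResult(breakeven_reduction=lo,
                               lost_sales_at_breakeven=float(l.mean()),
                               savings_at_breakeven=float(s.mean()),
                               ci=(lo, lo), tolerance_usd=tolerance_usd,
                               converged=True, curve=_curve_frame(evals))

    # bisect the (piecewise-constant under CRN) mean difference curve, then
    # interpolate the root within the final bracket
    a, b = lo, hi
    converged = False
    x_tol = 5e-3
    for _ in range(max_iter):
        mid = 0.5 * (a + b)
        gm = g(mid)
        if abs(gm) < tolerance_usd:
            a = b = mid
            converged = True
            break
        if gm < 0:
            a = mid
        else:
            b = mid
        if b - a < x_tol:
            converged = True
            break
    ga, gb = g(a), g(b)
    if a == b or gb == ga:
        root = 0.5 * (a + b)
        frac = 0.5
    else:
        frac = -ga / (gb - ga)
        root = a + frac * (b - a)
    sa, la = evals[a]
    sb, lb = evals[b]
    s_root = sa + frac * (sb - sa)
    l_root = la + frac * (lb - la)
    evals[root] = (np.asarray(s_root), np.asarray(l_root))

    # per-replicate roots via monotone interpolation over the evaluated grid
    rs = np.array(sorted(evals))
    diffs = np.stack([evals[r][0] - evals[r][1] for r in rs])  # (n_grid, n_rep)
    n_rep = diffs.shape[1]
    roots = np.empty(n_rep)
    for i in range(n_rep):
        d = diffs[:, i]
        sign_change = np.where((d[:-1] < 0) & (d[1:] >= 0))[0]
        if d[0] >= 0:
            roots[i] = rs[0]
        elif len(sign_change) == 0:
            roots[i] = rs[-1]
        else:
            j = sign_change[0]
            f = d[j] / (d[j] - d[j + 1])
            roots[i] = rs[j] + f * (rs[j + 1] - rs[j])

    return BreakEvenResult(
        breakeven_reduction=root,
        lost_sales_at_breakeven=float(np.mean(evals[root][1])),
        savings_at_breakeven=float(np.mean(evals[root][0])),
        ci=(float(np.percentile(roots, 2.5)), float(np.percentile(roots, 97.5))),
        tolerance_usd=tolerance_usd, converged=converged,
        curve=_curve_frame(evals))


def _curve_frame(evals: dict) -> pd.DataFrame:
    rs = sorted(evals)
    return pd.DataFrame({
        "reduction_oz_per_day": rs,
        "savings_usd_per_10k": [float(np.mean(evals[r][0])) for r in rs],
        "loss_usd_per_10k": [float(np.mean(evals[r][1])) for r in rs],
    })
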