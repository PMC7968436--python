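"""Deterministic cohort-expectation model mirroring the microsimulation.

Propagates expected disease prevalence, survival, and employment fractions
for age/sex start-cohorts under the same annual event order as the
microsimulation (mortality, incidence, employment transitions, aging).
Cross-condition dependence is approximated by conditional independence of
flags given age and sex, matching the generator's default.

Because QALYs and costs are linear in the utility/cost parameters given
these expected person-year components, this model supplies the coefficient
matrices for the least-squares world calibration, at negligible cost.  It is
a calibration device, not the simulator: the Monte Carlo engine remains the
instrument of record.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .economics import discount_factor
from .engine import AGE_CAP, N_COND
from .intervention import person_level_reductions
from .population import CONDITIONS, OBESITY_BMI_THRESHOLD


def population_mean_rr(world, reduction: float | None) -> dict[str, dict[str, float]]:
    """Population-average RR per outcome/channel at a mean reduction.

    Averages the per-person log-linear RR over the SSB consumption
    distribution (individual reductions capped at baseline intake); exact
    for expected event counts, which are linear in the per-person RR.
    """
    out = {"incidence": {}, "mortality": {}, "burden": {},
           "disutility_burden": {}, "other": 1.0}
    if reduction is None:
        for ch in ("incidence", "mortality", "burden", "disutility_burden"):
            out[ch] = {c: 1.0 for c in CONDITIONS}
        return out
    ssb = world.demographics.ssb_consumption_distribution.quantile_grid(2048)
    per_person = person_level_reductions(reduction, ssb)
    for c in CONDITIONS:
        for channel in ("incidence", "mortality", "burden", "disutility_burden"):
            out[channel][c] = float(np.mean(
                world.effect_sizes.rr_at(c, per_person, channel)))
    out["other"] = float(np.mean(
        world.effect_sizes.rr_at("other_mortality", per_person, "mortality")))
    return out


@dataclass
class ExpectationComponents:
    """Expected per-person person-year components over a horizon.

    All arrays are per condition (length 6) unless noted; `deaths_*` have a
    seventh entry for other-cause mortality.  Quantities are per initial
    person; multiply by 10,000 for the conventional reporting scale.
    """

    py_qaly_disc: float
    py_qaly_undisc: float
    page_disc: float                     # (age - 40)-weighted person-years
    page_undisc: float
    prevpy_disc: np.ndarray              # cost-burden weighted
    prevpy_undisc: np.ndarray
    prevpy_util_disc: np.ndarray         # disutility-burden weighted
    prevpy_util_undisc: np.ndarray
    prevpy_preret_disc: np.ndarray       # person-years below retirement age
    prevpy_enrolled_disc: np.ndarray     # employer-payer weighting
    prevpy_employed_disc: np.ndarray     # productivity weighting
    deaths_preret_disc: np.ndarray       # discounted premature deaths by cause (7)
    incident_cases: np.ndarray           # undiscounted counts (6)
    cause_deaths: np.ndarray             # undiscounted counts (7)
    horizon_years: int


def run_expectation(world, reduction: float | None = None,
                    horizon: int | str = "lifetime") -> ExpectationComponents:
    """Expected components for one scenario arm (reduction None = control)."""
    dem = world.demographics
    econ = world.econ
    rr = population_mean_rr(world, reduction)

    ages = dem.age_distribution.density_by_year()
    age0 = ages.index.to_numpy(dtype=float) + 0.5   # cohort mid-year ages
    sex_fracs = [("male", dem.sex_fractions.get("male", 0.5)),
                 ("female", dem.sex_fractions.get("female", 0.5))]
    cohorts = []
    for sex, frac in sex_fracs:
        for a, w in zip(age0, ages.to_numpy()):
            cohorts.append((a, sex == "male", w * frac))
    a0 = np.array([c[0] for c in cohorts])
    is_male = np.array([c[1] for c in cohorts])
    w = np.array([c[2] for c in cohorts])
    w = w / w.sum()
    nc = len(cohorts)

    n_years = (int(np.ceil(AGE_CAP - a0.min())) + 1 if horizon == "lifetime"
               else int(horizon))

    exposure = world.meta.get("exposure", "while_employed")

    S = np.ones(nc)
    p = np.zeros((nc, N_COND))
    for k, cond in enumerate(CONDITIONS):
        p[:, k] = dem.prevalence_for(cond, a0, is_male)

    cf = np.zeros((nc, N_COND))
    z6 = lambda: np.zeros(N_COND)  # noqa: E731
    comp = dict(py_qaly_disc=0.0, py_qaly_undisc=0.0, page_disc=0.0,
                page_undisc=0.0, prevpy_disc=z6(),
                prevpy_undisc=z6(), prevpy_util_disc=z6(), prevpy_util_undisc=z6(),
                prevpy_preret_disc=z6(),
                prevpy_enrolled_disc=z6(), prevpy_employed_disc=z6(),
                deaths_preret_disc=np.zeros(N_COND + 1),
                incident_cases=z6(), cause_deaths=np.zeros(N_COND + 1))

    for t in range(n_years):
        age = a0 + t
        disc = discount_factor(t, econ.discount_rate)
        working = age < econ.retirement_age
        emp_frac = np.where(working, (1.0 - econ.annual_attrition_rate) ** t, 0.0)
        enr_frac = emp_frac * dem.insurance_coverage_rate
        # exposure-weighted RR (intervention active while employed, unless the
        # world assumes the consumption change persists for life)
        def rr_t(base: float) -> np.ndarray:
            if exposure == "always":
                return np.full(nc, base)
            return emp_frac * base + (1.0 - emp_frac)

        q_bg = np.clip(world.background.lookup(age, is_male) * rr_t(rr["other"]), 0, 1)
        q_bg = np.where(age >= AGE_CAP - 1, 1.0, q_bg)

        d_cause = np.zeros((nc, N_COND))
        rem = 1.0 - q_bg
        hit = np.zeros((nc, N_COND))
        for k, cond in enumerate(CONDITIONS):
            dm = world.diseases[cond]
            if dm.contributes_to_mortality:
                cf[:, k] = dm.case_fatality.lookup(age, is_male)
                hit[:, k] = np.clip(cf[:, k] * rr_t(rr["mortality"][cond]), 0, 1)
                d_cause[:, k] = rem * p[:, k] * hit[:, k]
                rem = rem * (1.0 - p[:, k] * hit[:, k])
        q = q_bg + d_cause.sum(axis=1)
        surv = 1.0 - q

        # post-mortality selection, then incidence
        p_sel = np.empty_like(p)
        p_end = np.empty_like(p)
        inc_prob = np.zeros((nc, N_COND))
        for k, cond in enumerate(CONDITIONS):
            denom = p[:, k] * (1.0 - hit[:, k]) + (1.0 - p[:, k])
            p_sel[:, k] = np.where(denom > 0, p[:, k] * (1.0 - hit[:, k]) / denom, 0.0)
            inc_prob[:, k] = np.clip(
                world.diseases[cond].annual_incidence.lookup(age, is_male)
                * rr_t(rr["incidence"][cond]), 0, 1)
            p_end[:, k] = p_sel[:, k] + (1.0 - p_sel[:, k]) * inc_prob[:, k]

        py_eff = S * (surv + 0.5 * q)
        comp["py_qaly_disc"] += disc * float(w @ py_eff)
        comp["py_qaly_undisc"] += float(w @ py_eff)
        comp["page_disc"] += disc * float((w * (age - 40.0)) @ py_eff)
        comp["page_undisc"] += float((w * (age - 40.0)) @ py_eff)
        prevpy = (S * surv)[:, None] * p_end + 0.5 * (S * q)[:, None] * p
        # burden channel: prevalent-case cost/disutility scales while exposed.
        # employment-weighted person-years are fully exposed, so they carry
        # the full burden RR; population-wide person-years carry the mixture.
        b_mix = np.stack([rr_t(rr["burden"][c]) for c in CONDITIONS], axis=1)
        b_full = np.array([rr["burden"][c] for c in CONDITIONS])[None, :] \
            if exposure != "always" else b_mix
        bu_mix = np.stack([rr_t(rr["disutility_burden"][c]) for c in CONDITIONS],
                          axis=1)
        comp["prevpy_disc"] += disc * (w @ (prevpy * b_mix))
        comp["prevpy_undisc"] += (w @ (prevpy * b_mix))
        comp["prevpy_util_disc"] += disc * (w @ (prevpy * bu_mix))
        comp["prevpy_util_undisc"] += (w @ (prevpy * bu_mix))
        comp["prevpy_preret_disc"] += disc * ((w * working) @ (prevpy * b_mix))
        comp["prevpy_enrolled_disc"] += disc * ((w * enr_frac) @ (prevpy * b_full))
        comp["prevpy_employed_disc"] += disc * ((w * emp_frac) @ (prevpy * b_full))
        comp["incident_cases"] += (w * S * surv) @ ((1.0 - p_sel) * inc_prob)

        deaths_k = (w * S) @ d_cause
        deaths_other = float((w * S) @ q_bg)
        comp["cause_deaths"][:N_COND] += deaths_k
        comp["cause_deaths"][N_COND] += deaths_other
        pre = working.astype(float)
        comp["deaths_preret_disc"][:N_COND] += disc * ((w * S * pre) @ d_cause)
        comp["deaths_preret_disc"][N_COND] += disc * float((w * S * pre) @ q_bg)

        S = S * surv
        p = p_end

    return ExpectationComponents(horizon_years=n_years, **comp)


def obesity_mean_disutility(world) -> float:
    """Mean BMI-band obesity disutility among the obese at baseline."""
    bmi = world.demographics.bmi_distribution
    # conditional distribution of BMI above the threshold, via quantiles
    d = bmi._dist()
    p_thr = d.cdf(np.log(OBESITY_BMI_THRESHOLD))
    q = p_thr + (np.arange(512) + 0.5) / 512 * (1 - p_thr)
    vals = np.exp(d.ppf(q))
    return float(np.mean(world.utilities.obesity_disutility(vals)))


def expected_totals(world, comp: ExpectationComponents) -> dict[str, float | np.ndarray]:
    """QALY and cost totals (per person) implied by expected components."""
    u = world.utilities
    d = np.array([obesity_mean_disutility(world) if c == "obesity"
                  else u.disutilities.get(c, 0.0) for c in CONDITIONS])
    hc_y = np.array([world.costs.annual_health_cost.get(c, 0.0) for c in CONDITIONS])
    hc_o = np.array([world.costs.health_cost_postretirement(c) for c in CONDITIONS])
    pc = np.array([world.costs.annual_productivity_cost.get(c, 0.0) for c in CONDITIONS])
    f = world.costs.cpi_factor_to_dec2019
    dc = world.costs.death_productivity_cost * f
    s = world.econ.employer_cost_share
    prevpy_post = comp.prevpy_disc - comp.prevpy_preret_disc
    employer_by_cond = (s * hc_y * f * comp.prevpy_enrolled_disc
                       + pc * f * comp.prevpy_employed_disc
                       + dc * comp.deaths_preret_disc[:N_COND])
    healthcare_by_cond = f * (hc_y * comp.prevpy_preret_disc + hc_o * prevpy_post)
    slope = u.baseline_utility_age_slope
    return {
        "qalys_disc": (u.baseline_utility * comp.py_qaly_disc
                       - slope * comp.page_disc
                       - float(d @ comp.prevpy_util_disc)),
        "qalys_undisc": (u.baseline_utility * comp.py_qaly_undisc
                         - slope * comp.page_undisc
                         - float(d @ comp.prevpy_util_undisc)),
        "cost_employer_by_cond": employer_by_cond,
        "cost_employer": float(employer_by_cond.sum()),
        "cost_healthcare_by_cond": healthcare_by_cond,
        "cost_healthcare": float(healthcare_by_cond.sum()),
        "incident_plus_deaths": comp.incident_cases + comp.cause_deaths[:N_COND],
        "other_deaths": float(comp.cause_deaths[N_COND]),
    }


def expected_sales_loss(world, reduction: float, offset: float | None = None,
                        scale_to: float = 10000.0) -> float:
    """Expected discounted sales loss per `scale_to` persons (quantile grid)."""
    sales = world.sales
    econ = world.econ
    dem = world.demographics
    off = sales.compensatory_offset_fraction if offset is None else offset
    ssb = dem.ssb_consumption_distribution.quantile_grid(2048)
    atwork = sales.work_fraction_of_consumption * ssb
    oz = np.minimum(reduction, atwork)
    annual = float(np.mean(oz)) * sales.price_per_oz * sales.employer_profit_fraction \
        * sales.workdays_per_year * (1.0 - off)
    ages = dem.age_distribution.density_by_year()
    a0 = ages.index.to_numpy(dtype=float) + 0.5
    wts = ages.to_numpy() / ages.to_numpy().sum()
    total = 0.0
    for t in range(econ.employer_horizon):
        frac_working = float(wts[(a0 + t) < econ.retirement_age].sum())
        total += (discount_factor(t, econ.discount_rate)
                  * (1.0 - econ.annual_attrition_rate) ** t * frac_working * annual)
    return total * scale_to


def expected_employer_savings(world, reduction: float,
                              control: ExpectationComponents | None = None,
                              scale_to: float = 10000.0) -> float:
    """Expected discounted employer-perspective savings per `scale_to` persons."""
    horizon = world.econ.employer_horizon
    if control is None:
        control = run_expectation(world, None, horizon)
    ban = run_expectation(world, reduction, horizon)
    t_ctl = expected_totals(world, control)
    t_ban = expected_totals(world, ban)
    return (t_ctl["cost_employer"] - t_ban["cost_employer"]) * scale_to
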