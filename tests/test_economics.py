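"""Discounting, utilities, costs, and result aggregation."""

import copy

import numpy as np
import pytest

from ssbsim import (CostTable, EconomicAssumptions, UtilityTable,
                    aggregate_results, discount_factor, generate_population,
                    person_year_cost, person_year_utility, run_paired_scenarios)
from ssbsim.economics import CATEGORIES, EconRecorder
from ssbsim.engine import EventWindowRecorder
from ssbsim.population import CONDITIONS, ConfigError


class TestDiscounting:
    @pytest.mark.parametrize("year,rate,expected", [
        (0, 0.03, 1.0),
        (1, 0.03, 1.0 / 1.03),
        (10, 0.0, 1.0),
        (2, 0.03, 1.0 / 1.03 ** 2),
    ])
    def test_closed_forms(self, year, rate, expected):
        assert discount_factor(year, rate) == pytest.approx(expected)

    def test_negative_year_rejected(self):
        with pytest.raises(ValueError):
            discount_factor(-1, 0.03)


class TestPersonYearUtility:
    def test_no_conditions_returns_baseline(self):
        u = UtilityTable(baseline_utility=0.8, disutilities={"chd": 0.2})
        assert person_year_utility({}, bmi=24.0, utilities=u) == pytest.approx(0.8)

    def test_floor_at_zero(self):
        u = UtilityTable(baseline_utility=0.3,
                         disutilities={"chd": 0.25, "cva": 0.25})
        assert person_year_utility({"chd": True, "cva": True}, 24.0, u) == 0.0

    def test_bmi_band_disutility(self):
        u = UtilityTable(baseline_utility=0.9,
                         obesity_disutility_by_bmi=((30, 35, 0.05), (35, 60, 0.15)))
        assert person_year_utility({"obesity": True}, 33.0, u) == pytest.approx(0.85)
        assert person_year_utility({"obesity": True}, 45.0, u) == pytest.approx(0.75)

    def test_age_declining_baseline(self):
        u = UtilityTable(baseline_utility=0.9, baseline_utility_age_slope=0.004)
        assert person_year_utility({}, 24.0, u, age=60.0) == pytest.approx(0.82)

    def test_unknown_condition_rejected(self):
        with pytest.raises(ConfigError):
            person_year_utility({"gout": True}, 24.0, UtilityTable())


class TestPersonYearCost:
    def test_dead_person_costs_nothing(self):
        out = person_year_cost({"ckd": True}, enrolled=True, employed=True,
                               age=50, costs=CostTable(annual_health_cost={"ckd": 1000}),
                               econ=EconomicAssumptions(), alive=False)
        assert all(v == 0 for v in out.values())

    def test_single_condition_payer_composition(self):
        costs = CostTable(annual_health_cost={"ckd": 1000},
                          annual_productivity_cost={"ckd": 300})
        econ = EconomicAssumptions(employer_cost_share=0.8)
        out = person_year_cost({"ckd": True}, enrolled=True, employed=True,
                               age=50, costs=costs, econ=econ)
        assert out["health_employer"] == pytest.approx(800)
        assert out["health_other"] == pytest.approx(200)
        assert out["productivity"] == pytest.approx(300)

    def test_post_retirement_shifts_payer(self):
        costs = CostTable(annual_health_cost={"ckd": 1000})
        econ = EconomicAssumptions(employer_cost_share=0.8, retirement_age=65)
        out = person_year_cost({"ckd": True}, enrolled=True, employed=False,
                               age=70, costs=costs, econ=econ)
        assert out["health_employer"] == 0
        assert out["health_other"] == pytest.approx(1000)


@pytest.fixture(scope="module")
def small_replicates(calibrated_world):
    def recorders(arm, pop):
        return (EconRecorder(pop, calibrated_world.utilities, calibrated_world.costs,
                             calibrated_world.econ),
                EventWindowRecorder(calibrated_world.econ.employer_horizon))
    return run_paired_scenarios(
        lambda s: generate_population(400, calibrated_world.demographics, s),
        calibrated_world.diseases, calibrated_world.background, calibrated_world.effect_sizes,
        calibrated_world.effect, "lifetime", 3, seed=21,
        employment=calibrated_world.employment, recorder_factory=recorders)


class TestAggregation:
    def test_decomposition_sums_to_totals_each_replicate(self, calibrated_world,
                                                         small_replicates):
        import dataclasses
        for persp, horizon in (("employer", "employer"), ("healthcare", "lifetime")):
            econ = dataclasses.replace(calibrated_world.econ, perspective=persp)
            res = aggregate_results(small_replicates, calibrated_world.utilities,
                                    calibrated_world.costs, econ, horizon=horizon)
            rows = res.per_replicate
            q_sum = sum(rows[f"qalys_saved_{c}"] for c in CATEGORIES)
            np.testing.assert_allclose(q_sum, rows["qalys_saved_total"], atol=1e-8)
            c_sum = sum(rows[f"cost_saved_{c}"] for c in CATEGORIES)
            np.testing.assert_allclose(c_sum, rows["cost_saved_total"], atol=1e-6)

    def test_single_replicate_ci_collapses(self, calibrated_world, small_replicates):
        import dataclasses
        econ = dataclasses.replace(calibrated_world.econ, perspective="employer")
        res = aggregate_results(small_replicates[:1], calibrated_world.utilities,
                                calibrated_world.costs, econ, horizon="employer")
        t = res.table
        assert (t["qalys_saved"] == t["qalys_saved_ci_lo"]).all()
        assert (t["qalys_saved"] == t["qalys_saved_ci_hi"]).all()

    def test_payer_split_conserves_health_costs(self, small_replicates):
        rec = small_replicates[0].control.recorders[0]
        a = rec.totals("lifetime")
        total = a["health_employer"] + a["health_other"]
        assert np.all(total >= a["health_employer"])
        assert np.all(a["health_employer"] >= 0) and np.all(a["health_other"] >= 0)

    def test_qalys_bounded_by_person_years(self, calibrated_world, small_replicates):
        import dataclasses
        econ = dataclasses.replace(calibrated_world.econ, perspective="employer")
        res = aggregate_results(small_replicates, calibrated_world.utilities,
                                calibrated_world.costs, econ, horizon="employer")
        rows = res.per_replicate
        assert (rows["baseline_qalys_undisc"] <= 10_000 * 10).all()
        assert (rows["baseline_qalys_disc"] <= rows["baseline_qalys_undisc"]).all()

    def test_zero_discount_equalizes_disc_and_undisc(self, calibrated_world):
        import dataclasses
        world = copy.deepcopy(calibrated_world)
        world.econ = dataclasses.replace(world.econ, discount_rate=0.0)

        def recorders(arm, pop):
            return (EconRecorder(pop, world.utilities, world.costs, world.econ),)
        reps = run_paired_scenarios(
            generate_population(300, world.demographics, 5), world.diseases,
            world.background, world.effect_sizes, world.effect, 5, 1, seed=2,
            employment=world.employment, recorder_factory=recorders)
        rec = reps[0].control.recorders[0]
        assert np.allclose(rec.arrays["qaly_disc"], rec.arrays["qaly_undisc"])

    def test_zeroing_one_outcome_removes_only_its_rows(self, calibrated_world):
        """Under CRN, silencing dental costs/disutility leaves other rows
        unchanged (event streams are identical)."""
        import dataclasses

        def run(world):
            def recorders(arm, pop):
                return (EconRecorder(pop, world.utilities, world.costs, world.econ),
                        EventWindowRecorder(10))
            reps = run_paired_scenarios(
                generate_population(400, world.demographics, 9), world.diseases,
                world.background, world.effect_sizes, world.effect, 10, 2, seed=3,
                employment=world.employment, recorder_factory=recorders,
                exposure=world.meta.get("exposure", "while_employed"))
            econ = dataclasses.replace(world.econ, perspective="employer")
            return aggregate_results(reps, world.utilities, world.costs, econ,
                                     horizon="employer")

        base = run(calibrated_world)
        silenced = copy.deepcopy(calibrated_world)
        silenced.utilities.disutilities = dict(silenced.utilities.disutilities,
                                               dental=0.0)
        silenced.costs.annual_health_cost = dict(silenced.costs.annual_health_cost,
                                                 dental=0.0)
        silenced.costs.annual_health_cost_postretirement = dict(
            silenced.costs.annual_health_cost_postretirement, dental=0.0)
        silenced.costs.annual_productivity_cost = dict(
            silenced.costs.annual_productivity_cost, dental=0.0)
        quiet = run(silenced)
        assert quiet.table.loc["dental", "qalys_saved"] == 0
        assert quiet.table.loc["dental", "dollars_saved"] == 0
        for cond in CONDITIONS:
            if cond == "dental":
                continue
            assert quiet.table.loc[cond, "dollars_saved"] == pytest.approx(
                base.table.loc[cond, "dollars_saved"])
            assert quiet.table.loc[cond, "qalys_saved"] == pytest.approx(
                base.table.loc[cond, "qalys_saved"])
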