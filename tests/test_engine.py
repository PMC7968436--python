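"""Annual-cycle engine: rate tables, event mechanics, CRN, cohort oracle."""

import numpy as np
import pytest

from ssbsim import (BackgroundMortality, ConfigError, InterventionEffect,
                    RateTable, Scenario, generate_population, run_cohort,
                    run_paired_scenarios, step_year)
from ssbsim.engine import AGE_CAP
from ssbsim.population import CONDITIONS


class TestRateTable:
    def test_lookup_banded_by_sex_and_age(self):
        rt = RateTable([
            {"sex": "male", "age_lo": 16, "age_hi": 50, "rate": 0.1},
            {"sex": "male", "age_lo": 50, "age_hi": 110, "rate": 0.2},
            {"sex": "female", "age_lo": 16, "age_hi": 110, "rate": 0.05}])
        age = np.array([20.0, 60.0, 70.0])
        male = np.array([True, True, False])
        assert np.allclose(rt.lookup(age, male), [0.1, 0.2, 0.05])

    def test_bands_must_partition(self):
        with pytest.raises(ConfigError, match="partition"):
            RateTable([{"sex": "both", "age_lo": 16, "age_hi": 40, "rate": 0.1},
                       {"sex": "both", "age_lo": 50, "age_hi": 110, "rate": 0.1}])

    def test_bands_must_cover_range(self):
        with pytest.raises(ConfigError, match="cover"):
            RateTable([{"sex": "both", "age_lo": 16, "age_hi": 80, "rate": 0.1}])

    def test_hazard_conversion(self):
        rt = RateTable.from_hazard_records(
            [{"sex": "both", "age_lo": 16, "age_hi": 110, "rate": 0.3}])
        expected = 1 - np.exp(-0.3)
        assert rt.lookup(np.array([40.0]), np.array([True]))[0] == pytest.approx(expected)

    def test_scaling_clips_to_probability(self):
        rt = RateTable.constant(0.6).scaled(2.0)
        assert rt.lookup(np.array([40.0]), np.array([True]))[0] == 1.0
        with pytest.raises(ConfigError):
            RateTable.constant(0.1).scaled(-1.0)


class TestStepYear:
    def test_age_cap_forces_death(self, fixture_world):
        pop = generate_population(1, fixture_world.demographics, seed=0)
        person = pop[0]
        person.age = AGE_CAP - 0.5
        updated, event = step_year(person, fixture_world.diseases,
                                   fixture_world.background, Scenario.null(),
                                   np.random.default_rng(0))
        assert event.died and not updated.alive
        assert event.cause == "other"

    def test_dead_person_rejected(self, fixture_world):
        pop = generate_population(1, fixture_world.demographics, seed=0)
        person = pop[0]
        person.alive = False
        with pytest.raises(ValueError):
            step_year(person, fixture_world.diseases, fixture_world.background,
                      Scenario.null(), np.random.default_rng(0))


class TestRunCohort:
    def test_zero_mortality_conserves_person_years(self, fixture_world):
        n = 300
        pop = generate_population(n, fixture_world.demographics, seed=1)
        run = run_cohort(pop, fixture_world.diseases, fixture_world.background,
                         Scenario.null(), 10, 42, collect_ledger=True)
        assert run.person_years == 10 * n
        assert len(run.ledger) == 10 * n

    def test_death_year_included_in_ledger(self, fixture_world):
        # certain death from age 42: a 40-year-old gets exactly 3 rows
        world = fixture_world
        world.background = BackgroundMortality(RateTable([
            {"sex": "both", "age_lo": 16, "age_hi": 42, "rate": 0.0},
            {"sex": "both", "age_lo": 42, "age_hi": 110, "rate": 1.0}]))
        pop = generate_population(5, world.demographics, seed=2)  # all age 40
        run = run_cohort(pop, world.diseases, world.background, Scenario.null(),
                         10, 7, collect_ledger=True)
        counts = run.ledger.groupby("person_id").size()
        assert (counts == 3).all()
        assert run.ledger.groupby("person_id").died.sum().eq(1).all()

    def test_null_scenario_equals_explicit_unit_rrs(self, calibrated_world):
        pop = generate_population(500, calibrated_world.demographics, seed=3)
        unit = Scenario(rr_incidence={c: 1.0 for c in CONDITIONS},
                        rr_mortality={c: 1.0 for c in CONDITIONS},
                        rr_other_mortality=1.0)
        runs = [run_cohort(pop, calibrated_world.diseases, calibrated_world.background,
                           scen, 5, np.random.default_rng(99),
                           calibrated_world.employment, collect_ledger=True)
                for scen in (Scenario.null(), unit)]
        assert runs[0].ledger.equals(runs[1].ledger)
        assert runs[0].incident_cases == runs[1].incident_cases

    def test_empty_population_rejected(self, fixture_world):
        from ssbsim.population import Population
        pop = generate_population(1, fixture_world.demographics, seed=0)
        empty = Population.from_dataframe(pop.frame.iloc[:0])
        with pytest.raises(ValueError):
            run_cohort(empty, fixture_world.diseases, fixture_world.background,
                       Scenario.null(), 10, 0)


class TestPairedScenarios:
    def test_null_effect_gives_identical_arms(self, calibrated_world):
        effect = InterventionEffect(mean_reduction=0.0, ci_lower=0.0, ci_upper=0.0)
        reps = run_paired_scenarios(
            generate_population(400, calibrated_world.demographics, seed=4),
            calibrated_world.diseases, calibrated_world.background,
            calibrated_world.effect_sizes, effect, 10, 3, seed=5,
            employment=calibrated_world.employment)
        for rep in reps:
            assert rep.control.incident_cases == rep.ban.incident_cases
            assert rep.control.deaths_by_cause == rep.ban.deaths_by_cause
            assert np.array_equal(rep.control.state.flags, rep.ban.state.flags)

    def test_seed_determinism(self, calibrated_world):
        def run():
            return run_paired_scenarios(
                lambda s: generate_population(300, calibrated_world.demographics, s),
                calibrated_world.diseases, calibrated_world.background,
                calibrated_world.effect_sizes, calibrated_world.effect, 5, 2, seed=17,
                employment=calibrated_world.employment)
        a, b = run(), run()
        for ra, rb in zip(a, b):
            assert ra.reduction == rb.reduction
            assert ra.ban.incident_cases == rb.ban.incident_cases
            assert np.array_equal(ra.ban.state.alive, rb.ban.state.alive)

    def test_larger_reduction_never_increases_incident_cases(self, calibrated_world):
        pop = generate_population(2_000, calibrated_world.demographics, seed=6)
        counts = []
        for r in (0.5, 1.5, 3.0):
            reps = run_paired_scenarios(
                pop, calibrated_world.diseases, calibrated_world.background,
                calibrated_world.effect_sizes, calibrated_world.effect, 10, 1, seed=8,
                employment=calibrated_world.employment, forced_reduction=r)
            counts.append(reps[0].ban.incident_cases)
        for cond in CONDITIONS:
            assert counts[0][cond] >= counts[1][cond] >= counts[2][cond]


class TestCohortMatrixOracle:
    def test_single_disease_matches_two_state_markov(self, fixture_world):
        """Microsimulation expectation vs deterministic cohort closed form.

        One disease, constant incidence h, no mortality: the two-state chain
        gives prevalence p_t = 1 - (1 - h*rr)^t and expected incident cases
        n * (1 - p_T) summed; agreement within 3 Monte Carlo SEs at n=1e5.
        """
        n, h, rr, years = 100_000, 0.05, 0.90, 10
        world = fixture_world  # diabetes incidence 0.05, rr_ref 0.9, ssb >> dose
        pop = generate_population(n, world.demographics, seed=10)
        reps = run_paired_scenarios(pop, world.diseases, world.background,
                                    world.effect_sizes, world.effect, years, 1,
                                    seed=11, employment=world.employment,
                                    exposure="always")
        rep = reps[0]
        for arm, h_eff in (("control", h), ("ban", h * rr)):
            run = getattr(rep, arm)
            # survivors-without-disease follow (1 - h_eff)^t exactly
            expected_cases = n * (1 - (1 - h_eff) ** years)
            # cap dilution: a few low-consumption persons get a weaker RR
            if arm == "ban":
                ssb = pop.col("ssb_oz_per_day")
                rr_i = np.minimum(1.5, ssb) / 1.5 * np.log(rr)
                p_mean = 1 - np.mean((1 - h * np.exp(rr_i)) ** years)
                expected_cases = n * p_mean
            observed = run.incident_cases["diabetes"]
            se = np.sqrt(expected_cases * (1 - expected_cases / n))
            assert abs(observed - expected_cases) < 3 * se, arm

    def test_prevalence_trajectory_matches_matrix_model(self, fixture_world):
        n, h, years = 100_000, 0.05, 8
        pop = generate_population(n, fixture_world.demographics, seed=12)
        run = run_cohort(pop, fixture_world.diseases, fixture_world.background,
                         Scenario.null(), years, 13)
        k = CONDITIONS.index("diabetes")
        p_expected = 1 - (1 - h) ** years
        p_observed = run.state.flags[:, k].mean()
        se = np.sqrt(p_expected * (1 - p_expected) / n)
        assert abs(p_observed - p_expected) < 3 * se
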