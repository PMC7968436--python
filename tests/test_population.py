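"""Synthetic population generator: margins, invariants, IO."""

import numpy as np
import pandas as pd
import pytest

from ssbsim import ConfigError, generate_population, summarize_population
from ssbsim.population import (AgeBands, CONDITIONS, DemographicsConfig, GammaSSB,
                               Population, TruncLognormBMI)


def make_config(**overrides):
    base = dict(
        age_distribution=AgeBands(edges=[16.0, 28.0, 41.0, 52.0, 69.0],
                                  weights=[0.25, 0.25, 0.25, 0.25]),
        sex_fractions={"male": 0.517, "female": 0.483},
        race_ethnicity_fractions={"white": 0.54, "black": 0.114,
                                  "hispanic": 0.165, "asian": 0.181},
        occupational_class_fractions={"management": 0.189, "white_collar": 0.558,
                                      "blue_collar": 0.253},
        insurance_coverage_rate=0.92,
        baseline_prevalence_by_condition={"obesity": 0.395, "chd": 0.027,
                                          "cva": 0.006, "diabetes": 0.132,
                                          "ckd": 0.131, "dental": 0.959},
        bmi_distribution=TruncLognormBMI().calibrated_to_obesity(0.395),
        ssb_consumption_distribution=GammaSSB(mean_oz_per_day=11.7, shape=1.2),
    )
    base.update(overrides)
    return DemographicsConfig(**base)


class TestMargins:
    def test_margins_converge_to_config(self):
        """Empirical margins at n=1e5 match configured values within 3 SE."""
        n = 100_000
        pop = generate_population(n, make_config(), seed=0)
        s = summarize_population(pop)
        for cond, p in ((c, make_config().baseline_prevalence_by_condition[c])
                        for c in CONDITIONS):
            se = np.sqrt(p * (1 - p) / n)
            assert abs(s[f"prevalence_{cond}"] - p) < 3 * se + 1e-9, cond
        assert abs(s["sex_male"] - 0.517) < 3 * np.sqrt(0.25 / n)
        assert abs(s["age_mean"] - 40.875) < 0.15
        assert abs(s["age_q25"] - 28.0) < 0.5
        assert abs(s["age_q75"] - 52.0) < 0.5
        # gamma(shape=1.2): sd = mean/sqrt(shape)
        assert abs(s["ssb_oz_per_day_mean"] - 11.7) < 3 * (11.7 / np.sqrt(1.2 * n))

    def test_obesity_flag_equivalent_to_bmi_threshold(self):
        pop = generate_population(20_000, make_config(), seed=3)
        df = pop.frame
        assert (df.loc[df.obesity, "bmi"] >= 30).all()
        assert (df.loc[~df.obesity, "bmi"] < 30).all()

    def test_zero_prevalence_yields_no_flags(self):
        cfg = make_config(baseline_prevalence_by_condition={c: 0.0 for c in CONDITIONS},
                          bmi_distribution=TruncLognormBMI())
        pop = generate_population(10_000, cfg, seed=1)
        assert not pop.frame[list(CONDITIONS)].to_numpy().any()

    def test_subgroup_consumption_shift_table(self):
        cfg = make_config()
        shifted = make_config(ssb_multiplier_by_occupation={"blue_collar": 1.5})
        base = generate_population(50_000, cfg, seed=8).frame
        shift = generate_population(50_000, shifted, seed=8).frame
        blue = shift.occupational_class == "blue_collar"
        np.testing.assert_allclose(shift.loc[blue, "ssb_oz_per_day"],
                                   base.loc[blue, "ssb_oz_per_day"] * 1.5)
        np.testing.assert_allclose(shift.loc[~blue, "ssb_oz_per_day"],
                                   base.loc[~blue, "ssb_oz_per_day"])

    def test_conditional_prevalence_table_honored(self):
        table = [{"age_lo": 16, "age_hi": 45, "prevalence": 0.05},
                 {"age_lo": 45, "age_hi": 100, "prevalence": 0.30}]
        prevs = dict(make_config().baseline_prevalence_by_condition)
        prevs["diabetes"] = table
        pop = generate_population(100_000, make_config(
            baseline_prevalence_by_condition=prevs), seed=2)
        df = pop.frame
        young = df[df.age < 45]
        old = df[df.age >= 45]
        assert abs(young.diabetes.mean() - 0.05) < 3 * np.sqrt(0.05 * 0.95 / len(young))
        assert abs(old.diabetes.mean() - 0.30) < 3 * np.sqrt(0.30 * 0.70 / len(old))


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        a = generate_population(500, make_config(), seed=11).frame
        b = generate_population(500, make_config(), seed=11).frame
        pd.testing.assert_frame_equal(a, b)

    def test_different_seeds_differ(self):
        a = generate_population(500, make_config(), seed=11).frame
        b = generate_population(500, make_config(), seed=12).frame
        assert not a.equals(b)

    def test_single_person_repeatable(self):
        p1 = generate_population(1, make_config(), seed=5)[0]
        p2 = generate_population(1, make_config(), seed=5)[0]
        assert p1 == p2


class TestValidation:
    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ConfigError, match="sex_fractions"):
            generate_population(10, make_config(
                sex_fractions={"male": 0.6, "female": 0.6}), seed=0)

    def test_negative_population_size(self):
        with pytest.raises(ConfigError, match="n"):
            generate_population(0, make_config(), seed=0)

    def test_prevalence_out_of_range_names_condition(self):
        prevs = dict(make_config().baseline_prevalence_by_condition)
        prevs["ckd"] = 1.5
        with pytest.raises(ConfigError, match="ckd"):
            generate_population(10, make_config(
                baseline_prevalence_by_condition=prevs), seed=0)

    def test_age_support_bounds(self):
        with pytest.raises(ConfigError, match="age_distribution"):
            make_config(age_distribution=AgeBands(edges=[10.0, 30.0],
                                                  weights=[1.0])).validate()


class TestSummaryAndIO:
    def test_clone_population_zero_variance(self):
        pop = generate_population(1, make_config(), seed=7)
        clones = Population.from_dataframe(
            pd.concat([pop.frame] * 50, ignore_index=True))
        s = summarize_population(clones)
        assert s["age_q25"] == s["age_q75"]
        assert s["age_mean"] == pytest.approx(s["age_q25"], rel=1e-12)

    def test_empty_population_errors(self):
        empty = Population.from_dataframe(
            generate_population(1, make_config(), seed=0).frame.iloc[:0])
        with pytest.raises(ValueError):
            summarize_population(empty)

    def test_csv_roundtrip(self, tmp_path):
        pop = generate_population(200, make_config(), seed=9)
        path = tmp_path / "pop.csv"
        pop.to_csv(path)
        back = Population.from_csv(path)
        pd.testing.assert_frame_equal(pop.frame, back.frame, check_dtype=False)
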