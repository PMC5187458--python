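"""Phenotype statistics: AF-DCM summary, thresholds, grouping, sex tests."""

import numpy as np
import pytest

from wolfhound_dcm.cohort_io import DogRecord, HeartTest
from wolfhound_dcm.phenotype_stats import (
    GroupingPolicy,
    assign_groups,
    onset_quantile_threshold,
    pearson_chi2_2x2,
    sex_onset_comparison,
    summarize_af_dcm,
)
from wolfhound_dcm.synthetic_data import SimulationConfig, simulate_cohort


def _dog(dog_id, sex, tests, **kwargs):
    return DogRecord(
        dog_id=dog_id,
        sex=sex,
        heart_tests=[HeartTest(*t) for t in tests],
        **kwargs,
    )


def _affected_dog(dog_id, sex, af_age, dcm_age=None, last=None):
    tests = [(af_age, dcm_age == af_age, True)]
    if dcm_age is not None and dcm_age != af_age:
        tests.append((dcm_age, True, True))
    elif last is not None:
        tests.append((last, False, True))
    return _dog(dog_id, sex, tests)


class TestSummarizeAfDcm:
    def test_all_simultaneous_gives_zero_lags(self):
        cohort = [
            _affected_dog(f"d{i}", "male", 4.0, dcm_age=4.0) for i in range(5)
        ]
        summary = summarize_af_dcm(cohort)
        assert summary.af_to_dcm_lags == [0.0] * 5
        assert summary.n_simultaneous == summary.n_dcm_and_af == 5

    def test_identical_samples_give_t_zero(self):
        cohort = [
            _affected_dog("a", "male", 3.0, dcm_age=4.0),
            _affected_dog("b", "male", 3.0, dcm_age=5.0),
            _affected_dog("c", "male", 3.0, last=4.0),
            _affected_dog("d", "male", 3.0, last=5.0),
        ]
        summary = summarize_af_dcm(cohort)
        assert summary.af_to_dcm_lags == [1.0, 2.0]
        assert summary.af_only_durations == [1.0, 2.0]
        assert summary.t_statistic == pytest.approx(0.0, abs=1e-12)

    def test_t_statistic_matches_pooled_variance_formula(self):
        # lags {0.5, 1.0, 1.5} vs durations {1.0, 2.0, 3.0}:
        # sp^2 = (0.25 + 1.0)/2, t = -1/sqrt(sp^2 * 2/3) = -1.549193
        cohort = [
            _affected_dog("a", "male", 3.0, dcm_age=3.5),
            _affected_dog("b", "male", 3.0, dcm_age=4.0),
            _affected_dog("c", "male", 3.0, dcm_age=4.5),
            _affected_dog("d", "male", 3.0, last=4.0),
            _affected_dog("e", "male", 3.0, last=5.0),
            _affected_dog("f", "male", 3.0, last=6.0),
        ]
        summary = summarize_af_dcm(cohort)
        assert summary.t_statistic == pytest.approx(-1.5491933, abs=1e-6)

    def test_too_few_observations_flagged_as_undefined(self):
        cohort = [_affected_dog("a", "male", 3.0, dcm_age=4.0)]
        summary = summarize_af_dcm(cohort)
        assert summary.t_statistic is None and summary.p_value is None


class TestOnsetQuantileThreshold:
    def _cohort_from_onsets(self, onsets, sex="male"):
        return [
            _affected_dog(f"d{i}", sex, age, dcm_age=age)
            for i, age in enumerate(onsets)
        ]

    def test_eighty_percent_at_first_bin(self):
        cohort = self._cohort_from_onsets([2, 2, 2, 2, 9])
        assert onset_quantile_threshold(cohort, "male") == 2.0

    def test_uniform_onsets_brute_force_value(self):
        cohort = self._cohort_from_onsets([1, 2, 3, 4, 5])
        assert onset_quantile_threshold(cohort, "male") == 4.0

    def test_monotone_in_quantile(self):
        cohort = self._cohort_from_onsets([1.2, 2.7, 3.1, 4.9, 5.5, 6.0, 8.8])
        previous = 0.0
        for q in (0.2, 0.4, 0.6, 0.8, 0.95):
            threshold = onset_quantile_threshold(
                cohort, "male", GroupingPolicy(quantile=q)
            )
            assert threshold >= previous
            previous = threshold

    def test_no_affected_dogs_raises(self):
        clean = [_dog("d0", "male", [(7.0, False, False)])]
        with pytest.raises(ValueError):
            onset_quantile_threshold(clean, "male")

    def test_simulated_male_threshold_near_study_value(self):
        """At study-like defaults the 80% male threshold lands around the
        published 6.5 y figure."""
        thresholds = [
            onset_quantile_threshold(
                simulate_cohort(SimulationConfig(n_dogs=2000, seed=seed)), "male"
            )
            for seed in range(25)
        ]
        assert all(5.5 <= t <= 7.5 for t in thresholds)


class TestAssignGroups:
    POLICY = GroupingPolicy()

    def test_clean_old_female_is_unaffected(self):
        dog = _dog("f1", "female", [(9.0, False, False)], last_known_age_years=9.0)
        groups = assign_groups([dog], self.POLICY)
        assert dog.dog_id in groups.unaffected_ids

    def test_young_diagnosed_male_is_affected_regardless_of_age(self):
        dog = _dog("m1", "male", [(1.5, True, False)])
        groups = assign_groups([dog], self.POLICY)
        assert dog.dog_id in groups.affected_ids

    def test_old_female_with_stale_clean_test_is_excluded(self):
        dog = _dog(
            "f2", "female", [(8.0, False, False)], last_known_age_years=10.0
        )
        groups = assign_groups([dog], self.POLICY)
        assert groups.excluded[dog.dog_id] == "not_tested_since_threshold"

    def test_early_other_cause_death_is_excluded(self):
        dog = _dog(
            "m2",
            "male",
            [(3.0, False, False)],
            death_age_years=4.0,
            death_cause="other",
        )
        groups = assign_groups([dog], self.POLICY)
        assert groups.excluded[dog.dog_id] == "died_before_threshold"

    def test_young_dog_is_under_threshold(self):
        dog = _dog("m3", "male", [(3.0, False, False)], last_known_age_years=4.0)
        groups = assign_groups([dog], self.POLICY)
        assert groups.excluded[dog.dog_id] == "under_threshold"

    def test_unknown_birth_date_takes_precedence(self):
        dog = _dog(
            "m4",
            "male",
            [(3.0, False, False)],
            birth_known=False,
            death_age_years=4.0,
            death_cause="other",
        )
        groups = assign_groups([dog], self.POLICY)
        assert groups.excluded[dog.dog_id] == "unknown_age"

    def test_groups_partition_the_cohort(self, default_cohort):
        groups = assign_groups(default_cohort, self.POLICY)
        assert groups.n_classified + len(groups.excluded) == len(default_cohort)
        assert not groups.affected_ids & groups.unaffected_ids
        assert not set(groups.excluded) & (
            groups.affected_ids | groups.unaffected_ids
        )


class TestSexComparisons:
    def test_identical_age_lists_give_t_zero(self):
        cohort = [
            _affected_dog("m1", "male", 4.0, dcm_age=4.0),
            _affected_dog("m2", "male", 6.0, dcm_age=6.0),
            _affected_dog("f1", "female", 4.0, dcm_age=4.0),
            _affected_dog("f2", "female", 6.0, dcm_age=6.0),
        ]
        t, p, means = sex_onset_comparison(cohort)
        assert t == pytest.approx(0.0, abs=1e-12)
        assert means["male"] == means["female"] == 5.0

    def test_hand_computed_pooled_t(self):
        # males {4, 5}, females {6, 7} -> pooled t = -2.828
        cohort = [
            _affected_dog("m1", "male", 4.0, dcm_age=4.0),
            _affected_dog("m2", "male", 5.0, dcm_age=5.0),
            _affected_dog("f1", "female", 6.0, dcm_age=6.0),
            _affected_dog("f2", "female", 7.0, dcm_age=7.0),
        ]
        t, _, _ = sex_onset_comparison(cohort)
        assert t == pytest.approx(-2.8284271, abs=1e-6)

    def test_late_untested_diagnoses_can_be_excluded(self):
        late = _affected_dog("m9", "male", 8.0, dcm_age=8.0)  # first-ever test
        base = [
            _affected_dog("m1", "male", 4.0, dcm_age=4.0),
            _affected_dog("m2", "male", 5.0, dcm_age=5.0),
            _affected_dog("f1", "female", 6.0, dcm_age=6.0),
            # late female diagnosis but with an earlier clean screening,
            # so the exclusion rule keeps her
            _dog("f2", "female", [(5.0, False, False), (7.0, True, True)]),
        ]
        _, _, with_late = sex_onset_comparison(base + [late])
        _, _, without = sex_onset_comparison(
            base + [late], exclude_untested_late_diagnoses=True
        )
        assert with_late["male"] > without["male"]
        assert without["male"] == pytest.approx(4.5)

    def test_simulated_sex_onset_difference_detected(self):
        """Male onsets run ~1.3 y earlier at the defaults; the t-test
        should pick that up in essentially every seed at n=2000."""
        hits = 0
        for seed in range(20):
            cohort = simulate_cohort(SimulationConfig(n_dogs=2000, seed=seed))
            t, p, means = sex_onset_comparison(cohort)
            hits += means["male"] < means["female"] and p < 0.05
        assert hits >= 19


class TestSexProportion:
    def test_independent_table_gives_zero(self):
        chi2, df, p = pearson_chi2_2x2([[10, 10], [10, 10]])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert df == 1 and p == pytest.approx(1.0)

    def test_hand_computed_2x2(self):
        # N(ad-bc)^2 / (row x col products) = 100*500^2/(50*50*30*70) = 4.7619
        chi2, _, _ = pearson_chi2_2x2([[20, 30], [10, 40]])
        assert chi2 == pytest.approx(4.7619048, abs=1e-6)

    def test_equal_proportions_any_size_give_zero(self):
        chi2, _, _ = pearson_chi2_2x2([[30, 70], [15, 35]])
        assert chi2 == pytest.approx(0.0, abs=1e-12)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            pearson_chi2_2x2([[0, 0], [10, 40]])
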