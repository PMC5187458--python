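"""Phenotype-level statistics: the AF-DCM relationship, sex comparisons,
onset-quantile thresholds, and affected/unaffected group assignment.

AF is treated as a precursor of DCM, so any dog ever diagnosed with
either joins the affected group regardless of age. Unaffected controls
must have a clean heart test after a sex-specific age threshold - the
age by which 80% of ultimately affected dogs of that sex had been
diagnosed (6.5 y for males, 8.5 y for females in the study). Every
other dog is excluded with exactly one reason.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .cohort_io import FEMALE, MALE, DogRecord

EXCLUSION_REASONS = (
    "unknown_age",
    "died_before_threshold",
    "under_threshold",
    "not_tested_since_threshold",
)


@dataclass
class AfDcmSummary:
    n_dcm: int
    n_dcm_and_af: int
    n_simultaneous: int
    n_af_only: int
    af_to_dcm_lags: list[float]
    af_only_durations: list[float]
    t_statistic: float | None
    p_value: float | None

    @property
    def pct_dcm_with_af(self) -> float:
        return 100.0 * self.n_dcm_and_af / self.n_dcm if self.n_dcm else float("nan")

    @property
    def pct_simultaneous(self) -> float:
        return (
            100.0 * self.n_simultaneous / self.n_dcm_and_af
            if self.n_dcm_and_af
            else float("nan")
        )


@dataclass(frozen=True)
class GroupingPolicy:
    """Sex-specific unaffected-entry ages plus the quantile/binning used
    to derive them from onset data."""

    female_unaffected_min_age: float = 8.5
    male_unaffected_min_age: float = 6.5
    quantile: float = 0.8
    age_bin: float = 0.5

    def __post_init__(self):
        if self.female_unaffected_min_age <= 0 or self.male_unaffected_min_age <= 0:
            raise ValueError("thresholds must be positive")
        if not 0 < self.quantile < 1:
            raise ValueError("quantile must lie in (0, 1)")
        if self.age_bin <= 0:
            raise ValueError("age_bin must be positive")

    def threshold_for(self, sex: str) -> float:
        return (
            self.male_unaffected_min_age if sex == MALE else self.female_unaffected_min_age
        )


@dataclass
class GroupAssignment:
    affected_ids: set[str] = field(default_factory=set)
    unaffected_ids: set[str] = field(default_factory=set)
    excluded: dict[str, str] = field(default_factory=dict)

    @property
    def n_classified(self) -> int:
        return len(self.affected_ids) + len(self.unaffected_ids)

    def exclusion_counts(self) -> dict[str, int]:
        counts = {reason: 0 for reason in EXCLUSION_REASONS}
        for reason in self.excluded.values():
            counts[reason] += 1
        return counts


def _pooled_or_welch(a, b, welch: bool):
    return stats.ttest_ind(a, b, equal_var=not welch)


def summarize_af_dcm(
    cohort: Iterable[DogRecord],
    include_simultaneous: bool = True,
    welch: bool = False,
    simultaneous_tol: float = 1e-9,
) -> AfDcmSummary:
    """AF-to-DCM lag vs AF-only duration summary and t-test.

    Lag = first DCM age - first AF age for dually diagnosed dogs (>= 0
    by the precursor structure); duration = last heart-test age - first
    AF age for AF-only dogs. ``include_simultaneous=False`` drops the
    zero lags of same-day diagnoses from the t-test sample.
    """
    n_dcm = n_both = n_sim = n_af_only = 0
    lags: list[float] = []
    durations: list[float] = []
    for dog in cohort:
        dcm, af = dog.first_dcm_age, dog.first_af_age
        if dcm is not None:
            n_dcm += 1
            if af is not None:
                n_both += 1
                lag = dcm - af
                lags.append(lag)
                if abs(lag) <= simultaneous_tol:
                    n_sim += 1
        elif af is not None:
            n_af_only += 1
            durations.append(dog.last_test_age - af)
    sample = lags if include_simultaneous else [l for l in lags if l > simultaneous_tol]
    t = p = None
    if len(sample) >= 2 and len(durations) >= 2:
        t, p = _pooled_or_welch(sample, durations, welch)
        t, p = float(t), float(p)
    return AfDcmSummary(n_dcm, n_both, n_sim, n_af_only, lags, durations, t, p)


def onset_quantile_threshold(
    cohort: Iterable[DogRecord], sex: str, policy: GroupingPolicy = GroupingPolicy()
) -> float:
    """Smallest age-bin upper edge by which >= ``policy.quantile`` of
    ever-affected dogs of the given sex had been diagnosed."""
    onsets = [
        dog.first_diagnosis_age
        for dog in cohort
        if dog.sex == sex and dog.affected and dog.first_diagnosis_age is not None
    ]
    if not onsets:
        raise ValueError(f"no affected {sex} dogs with a known onset age")
    width = policy.age_bin
    edges = [math.ceil(a / width - 1e-9) * width for a in onsets]
    n = len(onsets)
    for edge in sorted(set(edges)):
        if sum(e <= edge for e in edges) / n >= policy.quantile:
            return edge
    return max(edges)


def assign_groups(
    cohort: Iterable[DogRecord], policy: GroupingPolicy = GroupingPolicy()
) -> GroupAssignment:
    """Partition the cohort into affected / unaffected / excluded.

    Affected: any DCM or AF diagnosis, at any age. Unaffected: a clean
    heart test strictly after the sex threshold. Otherwise excluded with
    the first matching reason in the order unknown_age,
    died_before_threshold, under_threshold, not_tested_since_threshold.
    """
    assignment = GroupAssignment()
    for dog in cohort:
        if dog.affected:
            assignment.affected_ids.add(dog.dog_id)
            continue
        threshold = policy.threshold_for(dog.sex)
        clean_after = any(
            t.age_years > threshold and not (t.dcm_diagnosed or t.af_diagnosed)
            for t in dog.heart_tests
        )
        if clean_after:
            assignment.unaffected_ids.add(dog.dog_id)
            continue
        reference = dog.reference_age
        if not dog.birth_known or reference is None:
            reason = "unknown_age"
        elif dog.death_age_years is not None and dog.death_age_years < threshold:
            reason = "died_before_threshold"
        elif reference <= threshold:
            reason = "under_threshold"
        else:
            reason = "not_tested_since_threshold"
        assignment.excluded[dog.dog_id] = reason
    return assignment


def sex_onset_comparison(
    cohort: Iterable[DogRecord],
    exclude_untested_late_diagnoses: bool = False,
    late_age: float = 6.5,
    welch: bool = False,
) -> tuple[float, float, dict[str, float]]:
    """Two-sample t-test on diagnosis ages, males vs females.

    With the exclusion flag set, dogs first diagnosed above ``late_age``
    at their very first heart test (no earlier screening to date the
    onset) are dropped - the sensitivity analysis for owner-reported
    late diagnoses.
    """
    samples: dict[str, list[float]] = {MALE: [], FEMALE: []}
    for dog in cohort:
        age = dog.first_diagnosis_age
        if age is None:
            continue
        if exclude_untested_late_diagnoses and age > late_age:
            earlier = [t for t in dog.heart_tests if t.age_years < age]
            if not earlier:
                continue
        samples[dog.sex].append(age)
    males, females = samples[MALE], samples[FEMALE]
    if len(males) < 2 or len(females) < 2:
        raise ValueError("need at least two affected dogs of each sex")
    t, p = _pooled_or_welch(males, females, welch)
    means = {MALE: float(np.mean(males)), FEMALE: float(np.mean(females))}
    return float(t), float(p), means


def pearson_chi2_2x2(table: Sequence[Sequence[float]]) -> tuple[float, int, float]:
    """Pearson chi-square on a 2x2 table, no continuity correction."""
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("zero marginal total")
    chi2, p, df, _ = stats.chi2_contingency(arr, correction=False)
    return float(chi2), int(df), float(p)


def sex_proportion_test(
    cohort: Iterable[DogRecord], policy: GroupingPolicy = GroupingPolicy()
) -> tuple[float, int, float]:
    """Affected/unaffected x sex chi-square on the classified groups."""
    cohort = list(cohort)
    assignment = assign_groups(cohort, policy)
    by_id = {dog.dog_id: dog for dog in cohort}
    table = np.zeros((2, 2))
    for ids, col in ((assignment.affected_ids, 0), (assignment.unaffected_ids, 1)):
        for dog_id in ids:
            row = 0 if by_id[dog_id].sex == MALE else 1
            table[row, col] += 1
    return pearson_chi2_2x2(table)
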