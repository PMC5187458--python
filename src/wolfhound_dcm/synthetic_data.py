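"""Synthetic cohort generator.

Emulates the statistical structure the association analysis assumes, so
every downstream stage runs without external data:

* genotypes drawn per locus under Hardy-Weinberg equilibrium at a
  configurable risk-allele frequency (loci independent, no LD);
* a lifetime disease indicator drawn with probability equal to the
  combined penetrance of the dog's multi-locus genotype;
* for diseased dogs a DCM onset age from a sex-specific truncated
  normal (study means 4.82 y male / 6.14 y female), with the AF onset
  equal to the DCM onset with probability 0.586 (simultaneous
  diagnoses) and otherwise up to 3 years earlier;
* competing mortality from other causes (exponential hazard), a
  per-dog data-freeze age, scheduled heart screenings at which the
  diagnosis flags are set, and per-locus genotyping dropout.

Everything is reproducible from the config seed. AF-without-DCM dogs
arise purely from censoring (AF onset observed, DCM onset beyond the
last screening); no separate AF-only disease class exists.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_io import FEMALE, MALE, CountRow, DogRecord, GenotypeCall, GenotypeCountTable, HeartTest
from .penetrance_fit import MODEL_KINDS, PenetranceModel, penetrance_vector

COMBINE_RULES = ("independent_or", "product_capped")


@dataclass(frozen=True)
class LocusSpec:
    """One simulated biallelic locus: HWE frequency of the risk allele
    plus the penetrance model it acts through."""

    name: str
    alleles: tuple[str, str]
    risk_allele: str
    allele_freq: float  # frequency of the risk allele
    model: str
    f0: float
    gamma: float

    def __post_init__(self):
        if self.risk_allele not in self.alleles:
            raise ValueError("risk allele must be one of the allele pair")
        if not 0 <= self.allele_freq <= 1:
            raise ValueError("allele_freq must lie in [0, 1]")
        if self.model not in MODEL_KINDS:
            raise ValueError(f"unknown model {self.model!r}")
        if not 0 < self.f0 <= 1:
            raise ValueError("f0 must lie in (0, 1]")
        if self.gamma < 1:
            raise ValueError("gamma must be >= 1")

    @property
    def other_allele(self) -> str:
        a, b = self.alleles
        return b if self.risk_allele == a else a

    def penetrances(self) -> np.ndarray:
        """Penetrance by risk-allele dosage (0, 1, 2 copies)."""
        return np.asarray(
            penetrance_vector(PenetranceModel(self.model, self.f0, self.gamma))
        )

    def hwe_probs(self) -> np.ndarray:
        """HWE genotype probabilities by risk-allele dosage (0, 1, 2)."""
        q = self.allele_freq
        p = 1 - q
        return np.array([p * p, 2 * p * q, q * q])

    def genotype_label(self, dosage: int) -> str:
        alleles = [self.other_allele] * (2 - dosage) + [self.risk_allele] * dosage
        return "".join(sorted(alleles))


def default_loci() -> tuple[LocusSpec, ...]:
    """Five loci mirroring the typed SNPs: study allele frequencies, the
    penetrance-model kinds the analysis selected, and modest effects."""
    return (
        LocusSpec("Chr1", ("C", "T"), "C", 0.82, "multiplicative", 0.06, 1.7),
        LocusSpec("Chr10", ("A", "C"), "C", 0.06, "multiplicative", 0.06, 1.3),
        LocusSpec("Chr15", ("C", "A"), "A", 0.37, "dominant", 0.06, 1.4),
        LocusSpec("Chr21", ("G", "A"), "G", 0.58, "dominant", 0.06, 1.8),
        LocusSpec("Chr37", ("G", "A"), "A", 0.41, "recessive", 0.06, 2.0),
    )


@dataclass(frozen=True)
class SimulationConfig:
    n_dogs: int = 500
    seed: int = 0
    sex_ratio_female: float = 0.65
    loci: tuple[LocusSpec, ...] = field(default_factory=default_loci)
    combine_rule: str = "independent_or"
    onset_mean_male: float = 4.82
    onset_sd_male: float = 2.0
    onset_mean_female: float = 6.14
    onset_sd_female: float = 2.0
    af_simultaneous_prob: float = 0.586
    af_lead_max_years: float = 3.0
    other_death_hazard: float = 0.1  # per year
    test_schedule_start: float = 1.5
    test_interval: float = 1.0
    study_end_age: float = 12.0
    genotype_missing_rate: float = 0.08

    def __post_init__(self):
        if self.n_dogs <= 0:
            raise ValueError("n_dogs must be positive")
        for name in ("sex_ratio_female", "af_simultaneous_prob", "genotype_missing_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.onset_sd_male <= 0 or self.onset_sd_female <= 0:
            raise ValueError("onset sds must be positive")
        if self.af_lead_max_years < 0:
            raise ValueError("af_lead_max_years must be >= 0")
        if self.combine_rule not in COMBINE_RULES:
            raise ValueError(f"unknown combine_rule {self.combine_rule!r}")
        if self.test_interval <= 0 or self.other_death_hazard <= 0:
            raise ValueError("test_interval and other_death_hazard must be positive")

    @classmethod
    def from_dict(cls, raw: dict) -> "SimulationConfig":
        raw = dict(raw)
        if "loci" in raw:
            raw["loci"] = tuple(
                LocusSpec(
                    name=l["name"],
                    alleles=tuple(l["alleles"]),
                    risk_allele=l["risk_allele"],
                    allele_freq=float(l["allele_freq"]),
                    model=l["model"],
                    f0=float(l["f0"]),
                    gamma=float(l["gamma"]),
                )
                for l in raw["loci"]
            )
        return cls(**raw)


def combined_penetrance(
    per_locus: np.ndarray, loci: Sequence[LocusSpec], rule: str
) -> np.ndarray:
    """Combine per-locus penetrances (columns = loci) into one lifetime
    disease probability per dog.

    independent_or: 1 - prod(1 - p_l) - each locus an independent
    chance to cause disease, bounded by construction. product_capped:
    baseline 1 - prod(1 - f0_l) scaled by the product of per-locus
    relative risks p_l/f0_l, capped at 1.
    """
    if rule == "independent_or":
        return 1.0 - np.prod(1.0 - per_locus, axis=1)
    f0s = np.array([spec.f0 for spec in loci])
    baseline = 1.0 - np.prod(1.0 - f0s)
    rr = np.prod(per_locus / f0s, axis=1)
    return np.minimum(1.0, baseline * rr)


def _truncnorm_ppf(u: np.ndarray, mean: float, sd: float, lo: float, hi: float):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.ppf(u, a, b, loc=mean, scale=sd)


def simulate_cohort(
    config: SimulationConfig, return_truth: bool = False
) -> list[DogRecord] | tuple[list[DogRecord], pd.DataFrame]:
    """Simulate a cohort of dog records.

    With ``return_truth=True`` also returns a DataFrame of the latent
    state per dog (disease indicator, true onset ages, freeze age) for
    parameter-recovery tests; the records themselves contain only what
    a real cohort file would.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_dogs
    loci = config.loci

    female = rng.random(n) < config.sex_ratio_female
    dosages = np.column_stack(
        [rng.choice(3, size=n, p=spec.hwe_probs()) for spec in loci]
    )
    per_locus = np.column_stack(
        [spec.penetrances()[dosages[:, j]] for j, spec in enumerate(loci)]
    )
    p_disease = combined_penetrance(per_locus, loci, config.combine_rule)
    diseased = rng.random(n) < p_disease

    u = rng.random(n)
    dcm_onset = np.empty(n)
    for sex_mask, mean, sd in (
        (female, config.onset_mean_female, config.onset_sd_female),
        (~female, config.onset_mean_male, config.onset_sd_male),
    ):
        dcm_onset[sex_mask] = _truncnorm_ppf(
            u[sex_mask], mean, sd, 1.0, config.study_end_age
        )
    simultaneous = rng.random(n) < config.af_simultaneous_prob
    lead = rng.uniform(0.0, config.af_lead_max_years, size=n)
    af_onset = np.where(simultaneous, dcm_onset, np.maximum(0.1, dcm_onset - lead))

    other_death = rng.exponential(1.0 / config.other_death_hazard, size=n)
    freeze_age = rng.uniform(0.5, config.study_end_age, size=n)
    end_obs = np.minimum(freeze_age, np.minimum(other_death, config.study_end_age))

    missing = rng.random((n, len(loci))) < config.genotype_missing_rate

    schedule = np.arange(
        config.test_schedule_start,
        config.study_end_age + 1e-9,
        config.test_interval,
    )

    records: list[DogRecord] = []
    width = len(str(n))
    for i in range(n):
        tests = []
        for age in schedule:
            if age > end_obs[i]:
                break
            tests.append(
                HeartTest(
                    age_years=round(float(age), 4),
                    dcm_diagnosed=bool(diseased[i] and age >= dcm_onset[i]),
                    af_diagnosed=bool(diseased[i] and age >= af_onset[i]),
                )
            )
        died = other_death[i] <= min(freeze_age[i], config.study_end_age)
        genotypes: dict[str, GenotypeCall | None] = {}
        for j, spec in enumerate(loci):
            if missing[i, j]:
                genotypes[spec.name] = None
            else:
                label = spec.genotype_label(int(dosages[i, j]))
                genotypes[spec.name] = GenotypeCall.from_label(spec.name, label)
        records.append(
            DogRecord(
                dog_id=f"sim{i:0{width}d}",
                sex=FEMALE if female[i] else MALE,
                neutered="unknown",
                birth_known=True,
                heart_tests=tests,
                last_known_age_years=round(float(end_obs[i]), 4),
                death_age_years=round(float(other_death[i]), 4) if died else None,
                death_cause="other" if died else "alive",
                genotypes=genotypes,
            )
        )
    if not return_truth:
        return records
    truth = pd.DataFrame(
        {
            "dog_id": [r.dog_id for r in records],
            "female": female,
            "p_disease": p_disease,
            "diseased": diseased,
            "dcm_onset": dcm_onset,
            "af_onset": af_onset,
            "other_death": other_death,
            "freeze_age": freeze_age,
            **{
                f"dosage_{spec.name}": dosages[:, j]
                for j, spec in enumerate(loci)
            },
        }
    )
    return records, truth


def case_control_distributions(
    loci: Sequence[LocusSpec], combine_rule: str = "independent_or"
) -> tuple[list[tuple[str, ...]], np.ndarray, np.ndarray]:
    """Exact genotype-combination distributions among cases and controls.

    Bayes inversion of HWE genotype probabilities against the combined
    penetrance: P(g|case) prop. P(g) f(g), P(g|control) prop.
    P(g)(1 - f(g)). Returns (labels, case probs, control probs).
    """
    dosage_sets = list(itertools.product(range(3), repeat=len(loci)))
    labels = []
    probs = np.empty(len(dosage_sets))
    pens = np.empty(len(dosage_sets))
    for k, combo in enumerate(dosage_sets):
        p = 1.0
        per_locus = np.empty((1, len(loci)))
        parts = []
        for j, spec in enumerate(loci):
            p *= spec.hwe_probs()[combo[j]]
            per_locus[0, j] = spec.penetrances()[combo[j]]
            parts.append(spec.genotype_label(combo[j]))
        probs[k] = p
        pens[k] = combined_penetrance(per_locus, loci, combine_rule)[0]
        labels.append(tuple(parts))
    case = probs * pens
    control = probs * (1.0 - pens)
    if case.sum() <= 0 or control.sum() <= 0:
        raise ValueError("degenerate penetrance: no cases or no controls possible")
    return labels, case / case.sum(), control / control.sum()


def population_prevalence(
    loci: Sequence[LocusSpec], combine_rule: str = "independent_or"
) -> float:
    """Lifetime disease probability of a random dog under HWE."""
    dosage_sets = list(itertools.product(range(3), repeat=len(loci)))
    total = 0.0
    for combo in dosage_sets:
        p = 1.0
        per_locus = np.empty((1, len(loci)))
        for j, spec in enumerate(loci):
            p *= spec.hwe_probs()[combo[j]]
            per_locus[0, j] = spec.penetrances()[combo[j]]
        total += p * combined_penetrance(per_locus, loci, combine_rule)[0]
    return total


def simulate_count_table(
    loci: Sequence[LocusSpec],
    n_affected: int,
    n_unaffected: int,
    seed: int,
    combine_rule: str = "independent_or",
) -> GenotypeCountTable:
    """Draw a case/control genotype count table directly (no ages).

    Counts are multinomial draws from the exact case and control
    genotype distributions implied by HWE + penetrance, reproducible
    from the seed.
    """
    if n_affected <= 0 or n_unaffected <= 0:
        raise ValueError("need positive affected and unaffected totals")
    labels, case_p, control_p = case_control_distributions(loci, combine_rule)
    rng = np.random.default_rng(seed)
    aff = rng.multinomial(n_affected, case_p)
    unaff = rng.multinomial(n_unaffected, control_p)
    rows = [
        CountRow(labels[k], int(aff[k]), int(unaff[k]))
        for k in range(len(labels))
    ]
    return GenotypeCountTable(tuple(spec.name for spec in loci), rows)
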