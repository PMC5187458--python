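"""Cohort data model and delimited-text I/O.

A cohort file is a CSV with one row per dog:

``dog_id, sex, neutered, birth_known, last_known_age_years, death_age_years,
death_cause, heart_tests, <locus>, <locus>, ...``

``heart_tests`` packs the screening history as semicolon-separated
``age:dcm:af`` triplets (e.g. ``"3.0:0:0;4.5:1:1"``); diagnosis flags are
sticky from the first screening at which the condition was seen. Every
column after ``heart_tests`` is a genotype column holding a two-letter
call such as ``CT``, or empty where the dog failed genotyping at that
locus.

Count-table files (one per locus or locus combination) are CSVs with the
genotype label column(s) followed by ``affected`` and ``unaffected``
integer counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

MALE = "male"
FEMALE = "female"
SEXES = (MALE, FEMALE)
_SEX_ALIASES = {"m": MALE, "male": MALE, "f": FEMALE, "female": FEMALE}
NEUTER_STATES = ("yes", "no", "unknown")
DEATH_CAUSES = ("dcm_af", "other", "unknown", "alive")
MAX_AGE_YEARS = 25.0

_FIXED_COLUMNS = [
    "dog_id",
    "sex",
    "neutered",
    "birth_known",
    "last_known_age_years",
    "death_age_years",
    "death_cause",
    "heart_tests",
]


class CohortSchemaError(ValueError):
    """The cohort file header does not match the documented schema."""


class CohortRowError(ValueError):
    """One or more rows violate the record invariants.

    ``problems`` maps dog_id -> list of human-readable violations.
    """

    def __init__(self, problems: Mapping[str, list[str]]):
        self.problems = dict(problems)
        detail = "; ".join(f"{d}: {', '.join(v)}" for d, v in self.problems.items())
        super().__init__(f"invalid cohort rows ({len(self.problems)}): {detail}")


class CountTableError(ValueError):
    """A count-table file or object violates its invariants."""


def normalize_sex(raw: str) -> str:
    key = raw.strip().lower()
    if key not in _SEX_ALIASES:
        raise ValueError(f"unrecognised sex {raw!r}")
    return _SEX_ALIASES[key]


@dataclass(frozen=True)
class GenotypeCall:
    """An unordered biallelic genotype call at one locus.

    Alleles are stored in canonical (alphabetical) order so that
    ``Aa`` and ``aA`` compare equal.
    """

    locus: str
    allele1: str
    allele2: str

    def __post_init__(self):
        if len(self.allele1) != 1 or len(self.allele2) != 1:
            raise ValueError("alleles must be single characters")
        if self.allele2 < self.allele1:
            a1, a2 = self.allele2, self.allele1
            object.__setattr__(self, "allele1", a1)
            object.__setattr__(self, "allele2", a2)

    @property
    def label(self) -> str:
        return self.allele1 + self.allele2

    @property
    def is_homozygous(self) -> bool:
        return self.allele1 == self.allele2

    @classmethod
    def from_label(cls, locus: str, label: str) -> "GenotypeCall":
        label = label.strip()
        if len(label) != 2:
            raise ValueError(f"genotype label {label!r} for {locus} is not two alleles")
        return cls(locus, label[0], label[1])


def genotype_key(label: str) -> str:
    """Canonical (alphabetical) form of a two-allele genotype label."""
    return "".join(sorted(label.strip()))


@dataclass(frozen=True)
class HeartTest:
    age_years: float
    dcm_diagnosed: bool
    af_diagnosed: bool


@dataclass
class DogRecord:
    """One animal: identity, sex, screening history, outcome, genotypes."""

    dog_id: str
    sex: str
    neutered: str = "unknown"
    birth_known: bool = True
    heart_tests: list[HeartTest] = field(default_factory=list)
    last_known_age_years: float | None = None
    death_age_years: float | None = None
    death_cause: str = "alive"
    genotypes: dict[str, GenotypeCall | None] = field(default_factory=dict)

    # -- derived phenotype views -------------------------------------------

    @property
    def first_dcm_age(self) -> float | None:
        ages = [t.age_years for t in self.heart_tests if t.dcm_diagnosed]
        return min(ages) if ages else None

    @property
    def first_af_age(self) -> float | None:
        ages = [t.age_years for t in self.heart_tests if t.af_diagnosed]
        return min(ages) if ages else None

    @property
    def affected(self) -> bool:
        return any(t.dcm_diagnosed or t.af_diagnosed for t in self.heart_tests)

    @property
    def first_diagnosis_age(self) -> float | None:
        ages = [a for a in (self.first_dcm_age, self.first_af_age) if a is not None]
        return min(ages) if ages else None

    @property
    def last_test_age(self) -> float | None:
        return self.heart_tests[-1].age_years if self.heart_tests else None

    @property
    def reference_age(self) -> float | None:
        """Best available age at end of observation (death, data freeze, or
        last screening)."""
        candidates = [
            a
            for a in (self.death_age_years, self.last_known_age_years, self.last_test_age)
            if a is not None
        ]
        return max(candidates) if candidates else None

    def genotype_at(self, locus: str) -> GenotypeCall | None:
        return self.genotypes.get(locus)

    def validate(self) -> list[str]:
        problems: list[str] = []
        if self.sex not in SEXES:
            problems.append(f"sex {self.sex!r} not in {SEXES}")
        if self.neutered not in NEUTER_STATES:
            problems.append(f"neutered {self.neutered!r} not in {NEUTER_STATES}")
        if self.death_cause not in DEATH_CAUSES:
            problems.append(f"death_cause {self.death_cause!r} not in {DEATH_CAUSES}")
        ages = [t.age_years for t in self.heart_tests]
        for a in ages:
            if not (0.0 <= a <= MAX_AGE_YEARS):
                problems.append(f"heart-test age {a} outside [0, {MAX_AGE_YEARS}]")
        if ages != sorted(ages):
            problems.append("heart tests not sorted by age")
        if self.death_age_years is not None:
            if ages and self.death_age_years < max(ages):
                problems.append("death age precedes last heart test")
            if not (0.0 <= self.death_age_years <= MAX_AGE_YEARS):
                problems.append(f"death age {self.death_age_years} outside range")
        return problems


# ---------------------------------------------------------------------------
# cohort CSV


def _encode_tests(tests: Sequence[HeartTest]) -> str:
    return ";".join(
        f"{t.age_years!r}:{int(t.dcm_diagnosed)}:{int(t.af_diagnosed)}" for t in tests
    )


def _decode_tests(raw: str) -> list[HeartTest]:
    tests: list[HeartTest] = []
    raw = raw.strip()
    if not raw:
        return tests
    for chunk in raw.split(";"):
        age_s, dcm_s, af_s = chunk.split(":")
        tests.append(HeartTest(float(age_s), bool(int(dcm_s)), bool(int(af_s))))
    return tests


def _fmt_optional(x: float | None) -> str:
    return "" if x is None else repr(x)


def write_cohort(records: Iterable[DogRecord], path: str | Path) -> None:
    """Write records as a cohort CSV; ``read_cohort`` inverts this exactly."""
    records = list(records)
    loci = sorted({locus for r in records for locus in r.genotypes})
    rows = []
    for r in records:
        row = {
            "dog_id": r.dog_id,
            "sex": r.sex,
            "neutered": r.neutered,
            "birth_known": str(int(r.birth_known)),
            "last_known_age_years": _fmt_optional(r.last_known_age_years),
            "death_age_years": _fmt_optional(r.death_age_years),
            "death_cause": r.death_cause,
            "heart_tests": _encode_tests(r.heart_tests),
        }
        for locus in loci:
            call = r.genotypes.get(locus)
            row[locus] = call.label if call is not None else ""
        rows.append(row)
    frame = pd.DataFrame(rows, columns=_FIXED_COLUMNS + loci)
    frame.to_csv(path, index=False)


def read_cohort(path: str | Path) -> list[DogRecord]:
    """Read a cohort CSV into records, collecting invariant violations.

    Raises :class:`CohortSchemaError` for a malformed header and
    :class:`CohortRowError` (listing offending dog ids) when any row is
    invalid.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _FIXED_COLUMNS if c not in frame.columns]
    if missing:
        raise CohortSchemaError(f"cohort file missing mandatory column(s): {missing}")
    loci = [c for c in frame.columns if c not in _FIXED_COLUMNS]

    records: list[DogRecord] = []
    problems: dict[str, list[str]] = {}
    for _, row in frame.iterrows():
        dog_id = row["dog_id"]
        errs: list[str] = []
        try:
            sex = normalize_sex(row["sex"])
        except ValueError as exc:
            sex = row["sex"]
            errs.append(str(exc))
        try:
            tests = _decode_tests(row["heart_tests"])
        except (ValueError, IndexError):
            tests = []
            errs.append(f"unparseable heart_tests {row['heart_tests']!r}")
        genotypes: dict[str, GenotypeCall | None] = {}
        for locus in loci:
            cell = row[locus].strip()
            if not cell:
                genotypes[locus] = None
            else:
                try:
                    genotypes[locus] = GenotypeCall.from_label(locus, cell)
                except ValueError as exc:
                    genotypes[locus] = None
                    errs.append(str(exc))

        def opt_age(cell: str, what: str) -> float | None:
            cell = cell.strip()
            if not cell:
                return None
            try:
                return float(cell)
            except ValueError:
                errs.append(f"unparseable {what} {cell!r}")
                return None

        record = DogRecord(
            dog_id=dog_id,
            sex=sex,
            neutered=row["neutered"].strip().lower() or "unknown",
            birth_known=row["birth_known"].strip() not in ("0", "no", "false"),
            heart_tests=tests,
            last_known_age_years=opt_age(row["last_known_age_years"], "last_known_age"),
            death_age_years=opt_age(row["death_age_years"], "death_age"),
            death_cause=row["death_cause"].strip().lower() or "alive",
            genotypes=genotypes,
        )
        errs.extend(record.validate())
        if errs:
            problems[dog_id] = errs
        records.append(record)
    if problems:
        raise CohortRowError(problems)
    return records


# ---------------------------------------------------------------------------
# genotype count tables


@dataclass(frozen=True)
class CountRow:
    """Affected/unaffected counts for one genotype (combination)."""

    genotypes: tuple[str, ...]
    affected: int
    unaffected: int

    @property
    def total(self) -> int:
        return self.affected + self.unaffected

    @property
    def risk(self) -> float:
        if self.total == 0:
            raise ZeroDivisionError("risk undefined for a zero-total row")
        return self.affected / self.total

    @property
    def label(self) -> str:
        return " + ".join(self.genotypes)


@dataclass
class GenotypeCountTable:
    """Per-genotype affected/unaffected counts for 1-3 loci.

    The unit every association statistic in this package consumes.
    """

    loci: tuple[str, ...]
    rows: list[CountRow]

    def __post_init__(self):
        self.loci = tuple(self.loci)
        if not 1 <= len(self.loci) <= 3:
            raise CountTableError("a count table covers 1 to 3 loci")
        labels = [r.genotypes for r in self.rows]
        if len(set(labels)) != len(labels):
            raise CountTableError("duplicate genotype label in count table")
        for r in self.rows:
            if len(r.genotypes) != len(self.loci):
                raise CountTableError("row genotype arity does not match loci")
            if r.affected < 0 or r.unaffected < 0:
                raise CountTableError("negative count")
            if not isinstance(r.affected, int) or not isinstance(r.unaffected, int):
                raise CountTableError("counts must be integers")
        if self.grand_total <= 0:
            raise CountTableError("count table is empty")

    @property
    def total_affected(self) -> int:
        return sum(r.affected for r in self.rows)

    @property
    def total_unaffected(self) -> int:
        return sum(r.unaffected for r in self.rows)

    @property
    def grand_total(self) -> int:
        return self.total_affected + self.total_unaffected

    def row(self, *genotypes: str) -> CountRow:
        for r in self.rows:
            if r.genotypes == tuple(genotypes):
                return r
        raise KeyError(genotypes)

    def to_dataframe(self) -> pd.DataFrame:
        data = {
            locus: [r.genotypes[i] for r in self.rows] for i, locus in enumerate(self.loci)
        }
        data["affected"] = [r.affected for r in self.rows]
        data["unaffected"] = [r.unaffected for r in self.rows]
        return pd.DataFrame(data)

    def write_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def read_count_table(path: str | Path) -> GenotypeCountTable:
    """Read a count-table CSV; the locus list is inferred from the header."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    cols = list(frame.columns)
    if cols[-2:] != ["affected", "unaffected"]:
        raise CountTableError(
            "count table must end with 'affected' and 'unaffected' columns"
        )
    loci = tuple(cols[:-2])
    rows = []
    for _, raw in frame.iterrows():
        counts = []
        for col in ("affected", "unaffected"):
            cell = raw[col].strip()
            try:
                value = int(cell)
            except ValueError:
                raise CountTableError(f"non-integer count {cell!r} in column {col}")
            counts.append(value)
        rows.append(CountRow(tuple(raw[l].strip() for l in loci), *counts))
    return GenotypeCountTable(loci, rows)
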