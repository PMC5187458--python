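"""In-silico PCR-RFLP validation and genotype calling from band patterns.

A restriction digest of the amplicon distinguishes the two alleles: the
``cut_allele`` carries the recognition site, so its product appears as
the digest fragments, while the other allele survives as a single
full-length band. Three gel patterns are therefore expected:

* one band at the amplicon length -> homozygote for the non-cut allele;
* digest fragments only -> homozygote for the cut allele;
* full-length band plus digest fragments -> heterozygote.

Band matching uses a +/- tolerance (default 10 bp, roughly the visual
resolution of a 2% agarose gel against a phix-HaeIII ladder in the
100-400 bp range). Fragments under 40 bp routinely run off or are too
faint to score, so they are treated as optional; the larger diagnostic
fragments are mandatory.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import yaml

from .cohort_io import DogRecord, CountRow, GenotypeCall, GenotypeCountTable

#: fragments at least this long must be visible for a digested call
MIN_VISIBLE_BP = 40
DEFAULT_TOLERANCE_BP = 10


class NoCallError(ValueError):
    """The observed band pattern matches none of the three templates."""


@dataclass(frozen=True)
class LocusDefinition:
    locus_name: str
    snp_id: str
    alleles: tuple[str, str]
    cut_allele: str
    enzyme: str
    recognition_site: str
    primer_set_label: str
    pcr_length: int
    digest_fragments: tuple[int, ...]

    def __post_init__(self):
        if self.cut_allele not in self.alleles:
            raise ValueError("cut_allele must be one of the allele pair")
        if self.pcr_length <= 0 or any(f <= 0 for f in self.digest_fragments):
            raise ValueError("fragment sizes must be positive")

    @property
    def uncut_allele(self) -> str:
        a, b = self.alleles
        return b if self.cut_allele == a else a


@dataclass(frozen=True)
class BandPattern:
    locus_name: str
    observed_bands: tuple[int, ...]

    def __post_init__(self):
        if not self.observed_bands:
            raise ValueError("empty band pattern")
        if any(b <= 0 for b in self.observed_bands):
            raise ValueError("band sizes must be positive")
        ordered = tuple(sorted(self.observed_bands, reverse=True))
        object.__setattr__(self, "observed_bands", ordered)


@dataclass(frozen=True)
class ValidationReport:
    locus_name: str
    primer_set_label: str
    passed: bool
    discrepancy_bp: int


def load_locus_definitions(path: str | Path | None = None) -> list[LocusDefinition]:
    """Load locus definitions from a YAML file (the packaged set of the
    five typed SNPs when ``path`` is None)."""
    if path is None:
        text = (
            resources.files("wolfhound_dcm").joinpath("data/loci.yaml").read_text()
        )
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    definitions = []
    for entry in raw["loci"]:
        for ps in entry["primer_sets"]:
            definitions.append(
                LocusDefinition(
                    locus_name=entry["locus_name"],
                    snp_id=entry["snp_id"],
                    alleles=tuple(entry["alleles"]),
                    cut_allele=entry["cut_allele"],
                    enzyme=entry["enzyme"],
                    recognition_site=entry["recognition_site"],
                    primer_set_label=ps["label"],
                    pcr_length=int(ps["pcr_length"]),
                    digest_fragments=tuple(int(f) for f in ps["digest_fragments"]),
                )
            )
    return definitions


def packaged_locus(locus_name: str, primer_set: str = "original") -> LocusDefinition:
    for d in load_locus_definitions():
        if d.locus_name == locus_name and d.primer_set_label == primer_set:
            return d
    raise KeyError((locus_name, primer_set))


def validate_locus_definition(locus: LocusDefinition) -> ValidationReport:
    """PASS iff the digest fragments sum to the amplicon length."""
    discrepancy = sum(locus.digest_fragments) - locus.pcr_length
    return ValidationReport(
        locus.locus_name, locus.primer_set_label, discrepancy == 0, discrepancy
    )


def expected_bands(locus: LocusDefinition, genotype: str) -> tuple[int, ...]:
    """The gel pattern a genotype should produce (small fragments included)."""
    key = "".join(sorted(genotype))
    uncut = "".join(sorted(locus.uncut_allele * 2))
    cut = "".join(sorted(locus.cut_allele * 2))
    het = "".join(sorted(locus.alleles))
    if key == uncut:
        return (locus.pcr_length,)
    if key == cut:
        return tuple(sorted(locus.digest_fragments, reverse=True))
    if key == het:
        return tuple(sorted((locus.pcr_length, *locus.digest_fragments), reverse=True))
    raise ValueError(f"genotype {genotype!r} impossible at {locus.locus_name}")


def call_genotype_from_bands(
    pattern: BandPattern,
    locus: LocusDefinition,
    tolerance_bp: int = DEFAULT_TOLERANCE_BP,
) -> GenotypeCall:
    """Call a genotype from an observed band pattern.

    Raises :class:`NoCallError`, with a diagnostic, for patterns that
    match none of the three templates or contain unexplained bands.
    """
    if tolerance_bp < 0:
        raise ValueError("tolerance must be non-negative")

    def near(band: int, size: int) -> bool:
        return abs(band - size) <= tolerance_bp

    bands = pattern.observed_bands
    has_uncut = any(near(b, locus.pcr_length) for b in bands)
    mandatory = [f for f in locus.digest_fragments if f >= MIN_VISIBLE_BP]
    all_mandatory_seen = bool(mandatory) and all(
        any(near(b, f) for b in bands) for f in mandatory
    )
    any_digest_seen = any(
        near(b, f) for b in bands for f in locus.digest_fragments
    )
    unexplained = [
        b
        for b in bands
        if not near(b, locus.pcr_length)
        and not any(near(b, f) for f in locus.digest_fragments)
    ]
    if unexplained:
        raise NoCallError(
            f"{locus.locus_name}: band(s) {unexplained} match neither the "
            f"{locus.pcr_length} bp amplicon nor digest fragments "
            f"{list(locus.digest_fragments)} (tolerance {tolerance_bp} bp)"
        )
    if has_uncut and all_mandatory_seen:
        a, b = locus.alleles
        return GenotypeCall(locus.locus_name, a, b)
    if has_uncut and not any_digest_seen:
        return GenotypeCall(locus.locus_name, locus.uncut_allele, locus.uncut_allele)
    if all_mandatory_seen and not has_uncut:
        return GenotypeCall(locus.locus_name, locus.cut_allele, locus.cut_allele)
    raise NoCallError(
        f"{locus.locus_name}: pattern {list(bands)} is not an uncut, fully "
        f"digested, or heterozygous template (mandatory fragments "
        f"{mandatory}, tolerance {tolerance_bp} bp)"
    )


def tabulate_genotype_counts(
    cohort: Iterable[DogRecord],
    locus_name: str,
    affected_ids: set[str],
    unaffected_ids: set[str],
) -> GenotypeCountTable:
    """Affected/unaffected counts per genotype at one locus.

    Dogs with a missing call at this locus, or outside the classified
    groups, are omitted; a missing call at one locus does not exclude a
    dog from other loci's tables.
    """
    cohort = list(cohort)
    if not any(locus_name in dog.genotypes for dog in cohort):
        raise KeyError(f"locus {locus_name!r} absent from cohort")
    counts: dict[str, list[int]] = {}
    for dog in cohort:
        call = dog.genotype_at(locus_name)
        if call is None:
            continue
        if dog.dog_id in affected_ids:
            slot = 0
        elif dog.dog_id in unaffected_ids:
            slot = 1
        else:
            continue
        counts.setdefault(call.label, [0, 0])[slot] += 1
    if not counts:
        raise ValueError(f"no classified dog carries a call at {locus_name}")
    rows = [
        CountRow((label,), aff, unaff)
        for label, (aff, unaff) in sorted(counts.items())
    ]
    return GenotypeCountTable((locus_name,), rows)


def allele_frequencies(
    source: GenotypeCountTable | Iterable[DogRecord],
    locus_name: str | None = None,
) -> dict[str, float]:
    """Allele frequencies = allele count / (2 x individuals called).

    Accepts a single-locus count table (affected + unaffected pooled:
    the study-wide frequency is computed irrespective of disease
    status) or an iterable of records plus ``locus_name``.
    """
    counts: dict[str, int] = {}
    if isinstance(source, GenotypeCountTable):
        if len(source.loci) != 1:
            raise ValueError("allele frequencies need a single-locus table")
        for row in source.rows:
            for allele in row.genotypes[0]:
                counts[allele] = counts.get(allele, 0) + row.total
    else:
        if locus_name is None:
            raise ValueError("locus_name required with a record iterable")
        for dog in source:
            call = dog.genotype_at(locus_name)
            if call is None:
                continue
            for allele in (call.allele1, call.allele2):
                counts[allele] = counts.get(allele, 0) + 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no genotype calls to count")
    return {allele: n / total for allele, n in sorted(counts.items())}
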