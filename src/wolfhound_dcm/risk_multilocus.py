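"""Genotype risks, relative risks against the population risk, pooling,
and multi-locus genotype-combination tables.

The reference group for every relative risk is the *whole classified
population* (here 72 affected of 95), even though it contains the
genotype subset, and the confidence interval treats the two as
independent samples (the log method: exp(ln RR -/+ z * sqrt(1/a - 1/n1
+ 1/c - 1/n2))). That is non-standard but is the construction that
reproduces the published intervals; a disjoint-complement reference is
available behind ``disjoint_reference=True``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from scipy import stats

from .association_tests import AssociationResult, bonferroni, chisq_gof, expected_affected
from .cohort_io import CountRow, DogRecord, GenotypeCountTable, genotype_key

POOLING_MODES = ("dominant", "recessive", "small_count", "none")


@dataclass(frozen=True)
class PoolingRule:
    """How to merge genotype classes at one locus before risk estimation."""

    mode: str = "none"
    min_count: int = 5

    def __post_init__(self):
        if self.mode not in POOLING_MODES:
            raise ValueError(f"unknown pooling mode {self.mode!r}")
        if self.min_count < 1:
            raise ValueError("min_count must be >= 1")


@dataclass
class RiskEstimate:
    genotypes: tuple[str, ...]
    affected: int
    total: int
    risk: float
    rr: float
    ci_low: float | None
    ci_high: float | None
    population_affected: int
    population_total: int
    significant: bool  # CI excludes 1

    @property
    def label(self) -> str:
        return " + ".join(self.genotypes)


def genotype_risk(affected: int, total: int) -> float:
    """Observed disease risk affected/total."""
    if total <= 0:
        raise ValueError("risk undefined for a zero total")
    return affected / total


def relative_risk_ci(
    affected: int,
    total: int,
    population_affected: int,
    population_total: int,
    confidence: float = 0.95,
    disjoint_reference: bool = False,
) -> RiskEstimate:
    """Genotype risk, relative risk vs the population, and log-method CI.

    ``affected = 0`` yields rr = 0 with an undefined (None) interval,
    flagged non-significant.
    """
    if total <= 0 or population_total <= 0:
        raise ValueError("totals must be positive")
    risk = genotype_risk(affected, total)
    ref_affected, ref_total = population_affected, population_total
    if disjoint_reference:
        ref_affected = population_affected - affected
        ref_total = population_total - total
        if ref_total <= 0 or ref_affected <= 0:
            raise ValueError("disjoint reference group is empty")
    ref_risk = ref_affected / ref_total
    if affected == 0:
        return RiskEstimate(
            ("?",), affected, total, risk, 0.0, None, None,
            population_affected, population_total, False,
        )
    rr = risk / ref_risk
    se = math.sqrt(
        1 / affected - 1 / total + 1 / ref_affected - 1 / ref_total
    )
    z = stats.norm.ppf(0.5 + confidence / 2)
    ci_low = rr * math.exp(-z * se)
    ci_high = rr * math.exp(z * se)
    return RiskEstimate(
        ("?",), affected, total, risk, rr, ci_low, ci_high,
        population_affected, population_total,
        significant=(ci_low > 1.0 or ci_high < 1.0),
    )


def _pooled_label(het: CountRow, hom: CountRow) -> str:
    return f"{het.genotypes[0]}/{hom.genotypes[0]}"


def pool_genotypes(table: GenotypeCountTable, rule: PoolingRule) -> GenotypeCountTable:
    """Merge genotype classes at a single locus.

    dominant/recessive merge the heterozygote with the like-penetrance
    homozygote (the higher-/lower-observed-risk homozygote
    respectively); small_count merges any homozygote with fewer than
    ``min_count`` dogs into the heterozygote class. Counts are conserved
    exactly.
    """
    if len(table.loci) != 1:
        raise ValueError("pooling applies to single-locus tables")
    if rule.mode == "none":
        return table

    het = next((r for r in table.rows if r.genotypes[0][0] != r.genotypes[0][1]), None)
    homs = [r for r in table.rows if r.genotypes[0][0] == r.genotypes[0][1]]
    if het is None:
        raise ValueError("no heterozygote class to pool into")

    def merged(rows: Sequence[CountRow], label: str) -> CountRow:
        return CountRow(
            (label,),
            sum(r.affected for r in rows),
            sum(r.unaffected for r in rows),
        )

    if rule.mode in ("dominant", "recessive"):
        if len(homs) != 2:
            raise ValueError("dominant/recessive pooling needs both homozygotes")
        ranked = sorted(homs, key=lambda r: (r.affected / r.total if r.total else 0.0,
                                             r.genotypes[0]))
        low, high = ranked
        partner = high if rule.mode == "dominant" else low
        keep = low if rule.mode == "dominant" else high
        rows = [keep, merged([het, partner], _pooled_label(het, partner))]
        rows.sort(key=lambda r: r.genotypes[0])
    else:  # small_count
        small = [r for r in homs if r.total < rule.min_count]
        if not small:
            return table
        pooled = merged([het] + small, "/".join(
            [het.genotypes[0]] + [r.genotypes[0] for r in small]
        ))
        keep = [r for r in homs if r.total >= rule.min_count]
        rows = sorted(keep, key=lambda r: r.genotypes[0]) + [pooled]
    if len(rows) < 2:
        raise ValueError("pooling would leave a single category")
    return GenotypeCountTable(table.loci, rows)


def _class_members(label: str) -> frozenset[str]:
    """Canonical genotype keys covered by a (possibly pooled) class label."""
    return frozenset(genotype_key(g) for g in label.split("/"))


def cross_tabulate(
    records: Iterable[DogRecord],
    affected_ids: set[str],
    unaffected_ids: set[str],
    loci: Sequence[str],
    class_labels: Mapping[str, Sequence[str]],
) -> GenotypeCountTable:
    """Joint affected/unaffected counts over combinations of pooled
    genotype classes at 2-3 loci.

    ``class_labels`` maps each locus to its (pooled) class labels, e.g.
    ``{"Chr21": ["AA", "GA/GG"]}``. Dogs outside the affected/unaffected
    groups or missing a call at any involved locus are excluded.
    """
    loci = list(loci)
    if not 2 <= len(loci) <= 3:
        raise ValueError("cross-tabulation covers 2 or 3 loci")
    lookup = {
        locus: {key: label for label in class_labels[locus]
                for key in _class_members(label)}
        for locus in loci
    }
    combos = list(itertools.product(*(class_labels[locus] for locus in loci)))
    counts = {c: [0, 0] for c in combos}
    n_used = 0
    for record in records:
        if record.dog_id in affected_ids:
            slot = 0
        elif record.dog_id in unaffected_ids:
            slot = 1
        else:
            continue
        keys = []
        for locus in loci:
            call = record.genotype_at(locus)
            if call is None:
                break
            label = lookup[locus].get(genotype_key(call.label))
            if label is None:
                break
            keys.append(label)
        else:
            counts[tuple(keys)][slot] += 1
            n_used += 1
    if n_used == 0:
        raise ValueError("no classified dog genotyped at every requested locus")
    rows = [CountRow(c, counts[c][0], counts[c][1]) for c in combos]
    return GenotypeCountTable(tuple(loci), rows)


def multilocus_association(
    table: GenotypeCountTable, family_size: int = 1
) -> AssociationResult:
    """Goodness-of-fit association test on genotype-combination classes.

    Expected affected counts come from the unaffected class proportions;
    combinations with zero expected count are skipped in the sum but
    counted in df = rows - 1.
    """
    aff = [r.affected for r in table.rows]
    unaff = [r.unaffected for r in table.rows]
    expected = expected_affected(aff, unaff)
    chi2, df, p = chisq_gof(aff, expected)
    excess = [
        a - e if e > 0 else 0.0 for a, e in zip(aff, expected)
    ]
    top = table.rows[max(range(len(aff)), key=lambda i: excess[i])]
    return AssociationResult(
        table.loci, "genotypic", chi2, df, p, bonferroni(p, family_size),
        family_size, top.label,
    )


def multilocus_risks(
    table: GenotypeCountTable,
    population_affected: int,
    population_total: int,
    confidence: float = 0.95,
) -> list[RiskEstimate]:
    """One RiskEstimate per genotype-combination row; rows whose CI
    excludes 1 are flagged significant."""
    estimates = []
    for row in table.rows:
        if row.total == 0:
            continue
        est = relative_risk_ci(
            row.affected, row.total, population_affected, population_total, confidence
        )
        est.genotypes = row.genotypes
        estimates.append(est)
    return estimates
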