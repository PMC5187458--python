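"""Association tests driven by unaffected-derived expected counts.

The study's construction differs from the usual 2xk contingency
expectation: the proportion of *unaffected* dogs in each category is
scaled to the affected total, giving expected affected counts, and the
goodness-of-fit chi-square of the observed affected counts against them
is reported. Categories whose expected count is zero contribute nothing
to the sum but keep their place in the degrees of freedom (df =
categories - 1). A conventional 2xk contingency chi-square is available
behind ``contingency=True`` for comparison.

Test types: ``allelic`` (counts doubled into allele space),
``pooled_dominant`` / ``pooled_recessive`` (two classes after pooling),
``trend`` (Cochran-Armitage with scores 0, 1, 2), ``genotypic`` (all
classes unpooled). Family-wise correction is Bonferroni:
p_corrected = min(1, p_raw x family_size).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .cohort_io import GenotypeCountTable

TEST_TYPES = ("allelic", "pooled_dominant", "pooled_recessive", "trend", "genotypic")


@dataclass
class AssociationResult:
    loci: tuple[str, ...]
    test_type: str
    chi2: float
    df: int
    p_raw: float
    p_corrected: float
    family_size: int
    risk_allele_or_genotype: str


def expected_affected(
    affected: Sequence[float], unaffected: Sequence[float]
) -> np.ndarray:
    """Expected affected count per category from unaffected proportions.

    expected_i = (unaffected_i / sum unaffected) x sum affected, so the
    expected counts conserve the affected total exactly.
    """
    affected = np.asarray(affected, dtype=float)
    unaffected = np.asarray(unaffected, dtype=float)
    if affected.shape != unaffected.shape:
        raise ValueError("category count mismatch")
    total_unaffected = unaffected.sum()
    total_affected = affected.sum()
    if total_unaffected <= 0:
        raise ValueError("no unaffected individuals: expected counts undefined")
    if total_affected <= 0:
        raise ValueError("no affected individuals: nothing to test")
    return unaffected / total_unaffected * total_affected


def chisq_gof(
    observed: Sequence[float],
    expected: Sequence[float],
    df_override: int | None = None,
) -> tuple[float, int, float]:
    """Goodness-of-fit chi-square with the zero-expected-cell rule.

    Cells with expected = 0 are skipped in the sum but still counted in
    df = (number of categories - 1), unless ``df_override`` is given.
    """
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if observed.shape != expected.shape:
        raise ValueError("length mismatch between observed and expected")
    mask = expected > 0
    if not mask.any():
        raise ValueError("every expected count is zero")
    chi2 = float(((observed[mask] - expected[mask]) ** 2 / expected[mask]).sum())
    df = df_override if df_override is not None else len(observed) - 1
    p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p


def bonferroni(p_raw: float, family_size: int) -> float:
    if not 0 < p_raw <= 1:
        raise ValueError("p_raw must lie in (0, 1]")
    if family_size < 1:
        raise ValueError("family_size must be >= 1")
    return min(1.0, p_raw * family_size)


def cochran_armitage(
    affected: Sequence[float],
    unaffected: Sequence[float],
    scores: Sequence[float] = (0.0, 1.0, 2.0),
) -> tuple[float, int, float]:
    """Cochran-Armitage trend chi-square (1 df) on a 2xk table."""
    a = np.asarray(affected, dtype=float)
    u = np.asarray(unaffected, dtype=float)
    s = np.asarray(scores, dtype=float)
    n = a + u
    big_n = n.sum()
    big_a = a.sum()
    if big_a == 0 or big_a == big_n:
        raise ValueError("trend test needs both affected and unaffected dogs")
    num = big_n * (s * a).sum() - big_a * (s * n).sum()
    den = big_a * (big_n - big_a) * (big_n * (s**2 * n).sum() - ((s * n).sum()) ** 2)
    if den <= 0:
        raise ValueError("degenerate score distribution")
    chi2 = float(big_n * num**2 / den)
    return chi2, 1, float(stats.chi2.sf(chi2, 1))


def contingency_chi2(
    affected: Sequence[float], unaffected: Sequence[float]
) -> tuple[float, int, float]:
    """Conventional 2xk Pearson contingency chi-square (no correction)."""
    table = np.array([affected, unaffected], dtype=float)
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(df), float(p)


def _allele_counts(table: GenotypeCountTable) -> tuple[list[str], np.ndarray, np.ndarray]:
    alleles = sorted({a for r in table.rows for a in r.genotypes[0]})
    aff = np.zeros(len(alleles))
    unaff = np.zeros(len(alleles))
    index = {a: i for i, a in enumerate(alleles)}
    for r in table.rows:
        for allele in r.genotypes[0]:
            aff[index[allele]] += r.affected
            unaff[index[allele]] += r.unaffected
    return alleles, aff, unaff


def run_association(
    table: GenotypeCountTable,
    test_type: str,
    family_size: int = 1,
    contingency: bool = False,
) -> AssociationResult:
    """Run one association test on a count table.

    Single-locus tables accept any test type; pooled tests pool a
    three-class table internally (using the observed-risk orientation)
    or accept an already two-class one. Multi-locus tables use
    ``genotypic``.
    """
    if test_type not in TEST_TYPES:
        raise ValueError(f"unknown test type {test_type!r}")

    if test_type == "allelic":
        labels, aff, unaff = _allele_counts(table)
    elif test_type in ("pooled_dominant", "pooled_recessive"):
        work = table
        if len(table.loci) == 1 and len(table.rows) > 2:
            from .risk_multilocus import PoolingRule, pool_genotypes

            mode = "dominant" if test_type == "pooled_dominant" else "recessive"
            work = pool_genotypes(table, PoolingRule(mode))
        labels = [r.label for r in work.rows]
        aff = np.array([r.affected for r in work.rows], dtype=float)
        unaff = np.array([r.unaffected for r in work.rows], dtype=float)
    elif test_type == "trend":
        if len(table.loci) != 1 or len(table.rows) != 3:
            raise ValueError("trend test needs an unpooled single-locus table")
        risks = [r.affected / r.total if r.total else 0.0 for r in table.rows]
        order = sorted(range(3), key=lambda i: (risks[i], table.rows[i].genotypes[0]))
        rows = [table.rows[i] for i in order]
        aff = np.array([r.affected for r in rows], dtype=float)
        unaff = np.array([r.unaffected for r in rows], dtype=float)
        chi2, df, p = cochran_armitage(aff, unaff)
        label = rows[-1].genotypes[0]
        return AssociationResult(
            table.loci, test_type, chi2, df, p, bonferroni(p, family_size),
            family_size, label,
        )
    else:  # genotypic
        labels = [r.label for r in table.rows]
        aff = np.array([r.affected for r in table.rows], dtype=float)
        unaff = np.array([r.unaffected for r in table.rows], dtype=float)

    if contingency:
        chi2, df, p = contingency_chi2(aff, unaff)
    else:
        expected = expected_affected(aff, unaff)
        chi2, df, p = chisq_gof(aff, expected)

    # the category most over-represented among affected dogs
    expected = expected_affected(aff, unaff)
    excess = np.where(expected > 0, aff - expected, 0.0)
    risk_label = labels[int(np.argmax(excess))]
    return AssociationResult(
        table.loci, test_type, chi2, df, p, bonferroni(p, family_size),
        family_size, risk_label,
    )
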