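"""Reconstructed study count tables.

The published analysis reports, for every genotype (and genotype
combination) at the three disease-associated loci, the disease risk to
two decimals together with the total number of dogs carrying it. Risk is
defined as affected/total, so the integer affected count is recoverable
as ``round(risk x total)``; the unaffected count follows by subtraction.
:func:`check_reconstruction` asserts, for every row, that the recovered
counts re-round to the printed risk - which they do, validating the
reconstruction exactly.

The whole-population reference is 72 affected of 95 classified dogs.
"""

from __future__ import annotations

from .cohort_io import CountRow, GenotypeCountTable

POPULATION_AFFECTED = 72
POPULATION_TOTAL = 95

#: Headline phenotype counts: dogs sampled, DCM diagnoses, DCM cases that
#: also carried an AF diagnosis, of which simultaneous, and AF-only dogs.
STUDY_COUNTS = {
    "n_sampled": 379,
    "n_dcm": 36,
    "n_dcm_and_af": 29,
    "n_simultaneous": 17,
    "n_af_only": 36,
    "n_unaffected_group": 23,
    "n_unaffected_female": 9,
    "n_unaffected_male": 14,
    "n_died_before_threshold": 20,
    "n_under_threshold": 234,
    "n_not_tested_since_threshold": 27,
    "n_unknown_age": 3,
}

#: Study-wide allele frequencies at the five typed loci (risk allele first
#: where one was reported).
ALLELE_FREQUENCIES = {
    "Chr1": {"C": 0.82, "T": 0.18},
    "Chr10": {"A": 0.94, "C": 0.06},
    "Chr15": {"C": 0.63, "A": 0.37},
    "Chr21": {"G": 0.58, "A": 0.42},
    "Chr37": {"G": 0.59, "A": 0.41},
}

# printed (genotype label(s), risk, total) rows, in printed order
_SINGLE = {
    "Chr1": [("CC", 0.81, 54), ("CT", 0.68, 22), ("TT", 0.5, 4)],
    "Chr21": [("AA", 0.61, 18), ("GA", 0.77, 39), ("GG", 0.82, 33)],
    "Chr37": [("AA", 0.85, 27), ("GA", 0.70, 23), ("GG", 0.73, 44)],
}

_SINGLE_POOLED = {
    "Chr1": [("CC", 0.81, 54), ("CT/TT", 0.65, 26)],
    "Chr21": [("AA", 0.61, 18), ("GA/GG", 0.79, 72)],
    "Chr37": [("AA", 0.85, 27), ("GA/GG", 0.72, 67)],
}

_PAIR = {
    ("Chr1", "Chr21"): [
        (("CC", "GG/GA"), 0.81, 48),
        (("CC", "AA"), 0.83, 6),
        (("CT/TT", "GG/GA"), 0.74, 19),
        (("CT/TT", "AA"), 0.33, 6),
    ],
    ("Chr1", "Chr37"): [
        (("CC", "GG/GA"), 0.79, 38),
        (("CC", "AA"), 0.88, 16),
        (("CT/TT", "GG/GA"), 0.61, 18),
        (("CT/TT", "AA"), 0.75, 8),
    ],
    ("Chr21", "Chr37"): [
        (("AA", "GG/GA"), 0.62, 13),
        (("AA", "AA"), 0.60, 5),
        (("GA/GG", "GG/GA"), 0.75, 52),
        (("GA/GG", "AA"), 0.89, 19),
    ],
}

_TRIPLE = [
    (("TT/CT", "AA", "AA"), 0.50, 2),
    (("TT/CT", "AA", "GG/GA"), 0.25, 4),
    (("TT/CT", "GA/GG", "AA"), 0.80, 5),
    (("TT/CT", "GA/GG", "GG/GA"), 0.73, 15),
    (("CC", "AA", "AA"), 0.50, 2),
    (("CC", "AA", "GG/GA"), 1.00, 4),
    (("CC", "GA/GG", "AA"), 0.93, 14),
    (("CC", "GA/GG", "GG/GA"), 0.76, 34),
]

SINGLE_LOCI = tuple(_SINGLE)
PAIR_LOCI = tuple(_PAIR)


def reconstruct_counts(risk: float, total: int) -> tuple[int, int]:
    """Recover (affected, unaffected) from a printed (risk, total) pair."""
    affected = int(risk * total + 0.5)
    return affected, total - affected


def _build(loci, rows) -> GenotypeCountTable:
    out = []
    for genotypes, risk, total in rows:
        if isinstance(genotypes, str):
            genotypes = (genotypes,)
        affected, unaffected = reconstruct_counts(risk, total)
        out.append(CountRow(tuple(genotypes), affected, unaffected))
    return GenotypeCountTable(tuple(loci), out)


def single_locus_table(locus: str, pooled: bool = False) -> GenotypeCountTable:
    source = _SINGLE_POOLED if pooled else _SINGLE
    return _build((locus,), source[locus])


def pair_table(locus1: str, locus2: str) -> GenotypeCountTable:
    return _build((locus1, locus2), _PAIR[(locus1, locus2)])


def triple_table() -> GenotypeCountTable:
    return _build(("Chr1", "Chr21", "Chr37"), _TRIPLE)


def check_reconstruction(atol: float = 0.005) -> list[str]:
    """Verify every reconstructed row re-rounds to its printed risk.

    Returns a list of mismatch descriptions (empty when, as published,
    the reconstruction is exact to 2 decimals everywhere).
    """
    mismatches = []
    everything = (
        [((l,), r) for l, rows in _SINGLE.items() for r in rows]
        + [((l,), r) for l, rows in _SINGLE_POOLED.items() for r in rows]
        + [(pair, r) for pair, rows in _PAIR.items() for r in rows]
        + [(("Chr1", "Chr21", "Chr37"), r) for r in _TRIPLE]
    )
    for loci, (genotypes, risk, total) in everything:
        affected, _ = reconstruct_counts(risk, total)
        # half-up rounding sits exactly on the boundary (e.g. 14/16 = 0.875
        # printed as 0.88), so the comparison carries a float guard
        if abs(affected / total - risk) > atol + 1e-9:
            mismatches.append(f"{loci} {genotypes}: {affected}/{total} != {risk}")
    return mismatches
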