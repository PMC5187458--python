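"""Single-locus penetrance models and model selection.

Each biallelic locus is described by a baseline risk ``f0`` - the
penetrance of the least risky homozygote a/a - and a penetrance
parameter ``gamma`` relating the remaining genotypes to it:

===============  =========  =========  ============
model            f(a/a)     f(a/A)     f(A/A)
===============  =========  =========  ============
multiplicative   f0         f0*gamma   f0*gamma^2
additive         f0         f0*gamma   2*f0*gamma
recessive        f0         f0         f0*gamma
dominant         f0         f0*gamma   f0*gamma
===============  =========  =========  ============

Penetrances are capped at 1. Fitting minimises the Pearson chi-square
between observed and model-expected affected counts per genotype class
(expected = penetrance x class total); the model with the smallest
minimised chi-square wins and dictates the appropriate association test
(multiplicative -> allelic, additive -> trend, dominant/recessive ->
the corresponding pooled two-class test).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .cohort_io import GenotypeCountTable

MODEL_KINDS = ("multiplicative", "additive", "dominant", "recessive")

#: association test appropriate for each penetrance model
TEST_FOR_MODEL = {
    "multiplicative": "allelic",
    "additive": "trend",
    "dominant": "pooled_dominant",
    "recessive": "pooled_recessive",
}

#: tie-break preference when minimised chi-squares coincide
_TIE_ORDER = ("multiplicative", "additive", "dominant", "recessive")

_F0_GRID = np.arange(0.005, 1.0 + 1e-9, 0.005)
_GAMMA_GRID = np.arange(0.1, 10.0 + 1e-9, 0.02)


class UnfittableTableError(ValueError):
    """Fewer than two non-empty genotype classes: nothing to fit."""


@dataclass(frozen=True)
class PenetranceModel:
    kind: str
    f0: float
    gamma: float

    def __post_init__(self):
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}")
        if not 0 < self.f0 <= 1:
            raise ValueError("f0 must lie in (0, 1]")
        if self.gamma < 0:
            raise ValueError("gamma must be non-negative")


def penetrance_vector(model: PenetranceModel) -> tuple[float, float, float]:
    """Penetrances (f_aa, f_Aa, f_AA), each capped at 1."""
    f0, g = model.f0, model.gamma
    if model.kind == "multiplicative":
        raw = (f0, f0 * g, f0 * g * g)
    elif model.kind == "additive":
        raw = (f0, f0 * g, 2 * f0 * g)
    elif model.kind == "recessive":
        raw = (f0, f0, f0 * g)
    else:  # dominant
        raw = (f0, f0 * g, f0 * g)
    return tuple(min(1.0, v) for v in raw)


@dataclass
class PenetranceFit:
    """A fitted model: parameters, expected affected counts, chi-square,
    and which homozygote played the low-risk a/a role."""

    model: PenetranceModel
    expected_affected: dict[str, float]
    chi2: float
    low_risk_allele: str
    risk_allele: str
    genotype_order: tuple[str, ...]  # (a/a, a/A, A/A) labels


def _orient(table: GenotypeCountTable):
    """Order the three genotype classes as (a/a, a/A, A/A) with a/a the
    homozygote of lower observed risk (tie -> alphabetical allele order)."""
    if len(table.loci) != 1:
        raise ValueError("penetrance fitting applies to single-locus tables")
    homs, het = {}, None
    alleles: set[str] = set()
    for row in table.rows:
        label = row.genotypes[0]
        alleles.update(label)
        if label[0] == label[1]:
            homs[label[0]] = row
        else:
            het = row
    if len(alleles) != 2:
        raise UnfittableTableError(f"could not infer an allele pair from {alleles}")
    # unobserved classes enter as empty (zero-count) rows and are skipped by
    # the chi-square
    from .cohort_io import CountRow

    a1, a2 = sorted(alleles)
    if het is None:
        het = CountRow((a1 + a2,), 0, 0)
    for allele in (a1, a2):
        homs.setdefault(allele, CountRow((allele + allele,), 0, 0))
    (al1, hom1), (al2, hom2) = sorted(homs.items())

    def risk(row):
        return row.affected / row.total if row.total else float("nan")

    r1, r2 = risk(hom1), risk(hom2)
    if np.isnan(r1) or np.isnan(r2) or r1 <= r2:
        low, high = (al1, al2)
        rows = (hom1, het, hom2)
    else:
        low, high = (al2, al1)
        rows = (hom2, het, hom1)
    return low, high, rows


def _chi2_surface(kind: str, totals: np.ndarray, observed: np.ndarray,
                  f0: np.ndarray, gamma: np.ndarray) -> np.ndarray:
    """Vectorised chi-square over a (f0, gamma) grid; empty classes skipped."""
    f0 = f0[:, None]
    gamma = gamma[None, :]
    if kind == "multiplicative":
        pens = [f0 * np.ones_like(gamma), f0 * gamma, f0 * gamma**2]
    elif kind == "additive":
        pens = [f0 * np.ones_like(gamma), f0 * gamma, 2 * f0 * gamma]
    elif kind == "recessive":
        pens = [f0 * np.ones_like(gamma), f0 * np.ones_like(gamma), f0 * gamma]
    else:
        pens = [f0 * np.ones_like(gamma), f0 * gamma, f0 * gamma]
    chi2 = np.zeros((f0.shape[0], gamma.shape[1]))
    for k in range(3):
        if totals[k] == 0:
            continue
        expected = np.minimum(pens[k], 1.0) * totals[k]
        chi2 += (observed[k] - expected) ** 2 / expected
    return chi2


def _chi2_point(kind: str, totals, observed, f0: float, gamma: float) -> float:
    vec = penetrance_vector(PenetranceModel(kind, f0, gamma))
    chi2 = 0.0
    for k in range(3):
        if totals[k] == 0:
            continue
        e = vec[k] * totals[k]
        chi2 += (observed[k] - e) ** 2 / e
    return chi2


def fit_model(table: GenotypeCountTable, kind: str) -> PenetranceFit:
    """Fit (f0, gamma) for one model kind by chi-square minimisation.

    A coarse vectorised grid over f0 in (0, 1] x gamma in [0.1, 10]
    locates the basin; a bounded Nelder-Mead polish refines it. Both
    stages are deterministic.
    """
    low, high, rows = _orient(table)
    totals = np.array([r.total for r in rows], dtype=float)
    observed = np.array([r.affected for r in rows], dtype=float)
    if np.count_nonzero(totals) < 2:
        raise UnfittableTableError("fewer than two non-empty genotype classes")

    surface = _chi2_surface(kind, totals, observed, _F0_GRID, _GAMMA_GRID)
    i, j = np.unravel_index(np.argmin(surface), surface.shape)
    x0 = np.array([_F0_GRID[i], _GAMMA_GRID[j]])

    res = minimize(
        lambda x: _chi2_point(kind, totals, observed, x[0], x[1]),
        x0,
        method="Nelder-Mead",
        bounds=[(1e-6, 1.0), (0.01, 50.0)],
        options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 2000},
    )
    f0, gamma = res.x
    chi2 = float(res.fun)
    model = PenetranceModel(kind, float(f0), float(gamma))
    vec = penetrance_vector(model)
    expected = {
        rows[k].genotypes[0]: vec[k] * rows[k].total for k in range(3)
    }
    return PenetranceFit(
        model=model,
        expected_affected=expected,
        chi2=chi2,
        low_risk_allele=low,
        risk_allele=high,
        genotype_order=tuple(r.genotypes[0] for r in rows),
    )


def select_model(table: GenotypeCountTable) -> tuple[str, dict[str, PenetranceFit]]:
    """Fit all four penetrance models and return the best-fitting kind.

    The winner minimises chi-square; exact ties fall back on the fixed
    preference order multiplicative > additive > dominant > recessive.
    """
    fits: dict[str, PenetranceFit] = {}
    for kind in MODEL_KINDS:
        fits[kind] = fit_model(table, kind)
    winner = min(_TIE_ORDER, key=lambda k: (round(fits[k].chi2, 9), _TIE_ORDER.index(k)))
    return winner, fits
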