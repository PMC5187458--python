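"""End-to-end analysis driver and report writing.

Two entry points:

* :func:`run_printed_fixture_analysis` re-runs the whole association
  analysis on the packaged reconstructed study tables (population 72
  affected / 95 classified): per-locus model selection, the matched
  association test with Bonferroni family 5, pooled risk/RR tables,
  all locus pairs (family 3), and the three-locus combination.
* :func:`run_pipeline` drives the same stages from a cohort file (or a
  simulation config): phenotype summary -> group assignment -> per-locus
  tabulation -> model selection -> association -> RR tables -> pairs ->
  full combination, writing one machine-readable CSV/JSON per stage
  plus a combined text report.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import study_fixtures as fx
from .association_tests import AssociationResult, run_association
from .cohort_io import DogRecord, GenotypeCountTable, read_cohort
from .penetrance_fit import TEST_FOR_MODEL, select_model
from .phenotype_stats import (
    GroupingPolicy,
    assign_groups,
    onset_quantile_threshold,
    sex_onset_comparison,
    sex_proportion_test,
    summarize_af_dcm,
)
from .rflp_typing import allele_frequencies, tabulate_genotype_counts
from .risk_multilocus import (
    PoolingRule,
    cross_tabulate,
    multilocus_association,
    multilocus_risks,
    pool_genotypes,
)
from .synthetic_data import SimulationConfig, simulate_cohort

#: pooling rule implied by each selected penetrance model
_POOLING_FOR_MODEL = {
    "multiplicative": PoolingRule("small_count"),
    "additive": PoolingRule("small_count"),
    "dominant": PoolingRule("dominant"),
    "recessive": PoolingRule("recessive"),
}


@dataclass
class PipelineConfig:
    cohort_path: str | None = None
    simulation: SimulationConfig | None = None
    policy: GroupingPolicy = field(default_factory=GroupingPolicy)
    loci: list[str] | None = None  # None -> every genotyped locus
    single_family_size: int = 5
    pair_family_size: int = 3
    population_override: tuple[int, int] | None = None
    out_dir: str | Path = "results"
    seed: int = 0

    def __post_init__(self):
        if self.single_family_size < 1 or self.pair_family_size < 1:
            raise ValueError("family sizes must be >= 1")
        if (self.cohort_path is None) == (self.simulation is None):
            raise ValueError("provide exactly one of cohort_path or simulation")


def _association_row(res: AssociationResult) -> dict:
    return {
        "loci": "+".join(res.loci),
        "test": res.test_type,
        "chi2": res.chi2,
        "df": res.df,
        "p_raw": res.p_raw,
        "p_corrected": res.p_corrected,
        "family_size": res.family_size,
        "risk_label": res.risk_allele_or_genotype,
    }


def _risk_frame(estimates) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "genotype": est.label,
                "affected": est.affected,
                "total": est.total,
                "risk": est.risk,
                "rr": est.rr,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "significant": est.significant,
            }
            for est in estimates
        ]
    )


def run_printed_fixture_analysis() -> dict:
    """Re-run the association analysis on the reconstructed study tables.

    Returns a nested dict: per-locus model selection + test + pooled
    risks, pairwise and triple combination tests and risks, and the
    headline phenotype proportions.
    """
    mismatches = fx.check_reconstruction()
    if mismatches:
        raise AssertionError(f"fixture reconstruction drifted: {mismatches}")
    pop_aff, pop_total = fx.POPULATION_AFFECTED, fx.POPULATION_TOTAL

    singles = {}
    pooled_tables: dict[str, GenotypeCountTable] = {}
    for locus in fx.SINGLE_LOCI:
        table = fx.single_locus_table(locus)
        winner, fits = select_model(table)
        test = run_association(table, TEST_FOR_MODEL[winner],
                               family_size=5)
        pooled = pool_genotypes(table, _POOLING_FOR_MODEL[winner])
        pooled_tables[locus] = pooled
        risks = multilocus_risks(pooled, pop_aff, pop_total)
        singles[locus] = {
            "model": winner,
            "risk_allele": fits[winner].risk_allele,
            "gamma": fits[winner].model.gamma,
            "f0": fits[winner].model.f0,
            "model_chi2": fits[winner].chi2,
            "association": test,
            "pooled_table": pooled,
            "risks": risks,
        }

    pairs = {}
    for l1, l2 in fx.PAIR_LOCI:
        table = fx.pair_table(l1, l2)
        pairs[(l1, l2)] = {
            "association": multilocus_association(table, family_size=3),
            "risks": multilocus_risks(table, pop_aff, pop_total),
            "table": table,
        }

    triple = fx.triple_table()
    triple_result = {
        "association": multilocus_association(triple, family_size=1),
        "risks": multilocus_risks(triple, pop_aff, pop_total),
        "table": triple,
    }

    counts = fx.STUDY_COUNTS
    phenotype = {
        "pct_dcm_with_af": 100.0 * counts["n_dcm_and_af"] / counts["n_dcm"],
        "pct_simultaneous": 100.0 * counts["n_simultaneous"] / counts["n_dcm_and_af"],
        "population_risk": pop_aff / pop_total,
        "population": (pop_aff, pop_total),
    }
    return {
        "phenotype": phenotype,
        "singles": singles,
        "pairs": pairs,
        "triple": triple_result,
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage on a cohort and write per-stage outputs.

    Deterministic given the config (and seed, when simulating); outputs
    land under ``config.out_dir``. Returns the in-memory results dict.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.cohort_path is not None:
        cohort = read_cohort(config.cohort_path)
    else:
        sim = config.simulation
        if sim.seed != config.seed:
            sim = SimulationConfig(**{**sim.__dict__, "seed": config.seed})
        cohort = simulate_cohort(sim)
    if not cohort:
        raise ValueError("empty cohort")

    results: dict = {}

    # phenotype stage
    summary = summarize_af_dcm(cohort)
    try:
        t_sex, p_sex, means = sex_onset_comparison(cohort)
    except ValueError:
        t_sex = p_sex = float("nan")
        means = {}
    thresholds = {}
    for sex in ("male", "female"):
        try:
            thresholds[sex] = onset_quantile_threshold(cohort, sex, config.policy)
        except ValueError:
            thresholds[sex] = None
    results["phenotype"] = {
        "af_dcm": summary,
        "sex_onset_t": t_sex,
        "sex_onset_p": p_sex,
        "onset_means": means,
        "onset_thresholds": thresholds,
    }
    with open(out / "phenotype.json", "w") as fh:
        json.dump(
            {
                "n_dcm": summary.n_dcm,
                "n_dcm_and_af": summary.n_dcm_and_af,
                "n_simultaneous": summary.n_simultaneous,
                "n_af_only": summary.n_af_only,
                "lag_vs_duration_t": summary.t_statistic,
                "lag_vs_duration_p": summary.p_value,
                "sex_onset_t": t_sex,
                "sex_onset_p": p_sex,
                "onset_means": means,
                "onset_thresholds": thresholds,
            },
            fh,
            indent=2,
        )

    # group assignment
    assignment = assign_groups(cohort, config.policy)
    results["assignment"] = assignment
    if config.population_override is not None:
        pop_aff, pop_total = config.population_override
    else:
        pop_aff = len(assignment.affected_ids)
        pop_total = assignment.n_classified
    results["population"] = (pop_aff, pop_total)

    try:
        chi2_sex, df_sex, p_sexprop = sex_proportion_test(cohort, config.policy)
    except ValueError:
        chi2_sex = df_sex = p_sexprop = float("nan")
    results["sex_proportion"] = (chi2_sex, df_sex, p_sexprop)

    loci = config.loci
    if loci is None:
        loci = sorted({locus for dog in cohort for locus in dog.genotypes})

    # per-locus: tabulate, fit, associate, risks
    association_rows = []
    singles: dict[str, dict] = {}
    significant: list[str] = []
    for locus in loci:
        table = tabulate_genotype_counts(
            cohort, locus, assignment.affected_ids, assignment.unaffected_ids
        )
        freqs = allele_frequencies(cohort, locus)
        try:
            winner, fits = select_model(table)
        except ValueError as exc:
            singles[locus] = {"error": f"model fit failed: {exc}"}
            continue
        test = run_association(
            table, TEST_FOR_MODEL[winner], family_size=config.single_family_size
        )
        pooled = pool_genotypes(table, _POOLING_FOR_MODEL[winner])
        risks = multilocus_risks(pooled, pop_aff, pop_total)
        singles[locus] = {
            "table": table,
            "allele_freqs": freqs,
            "model": winner,
            "fit": fits[winner],
            "association": test,
            "pooled_table": pooled,
            "risks": risks,
        }
        association_rows.append(_association_row(test))
        if test.p_corrected < 0.05:
            significant.append(locus)
    results["singles"] = singles
    results["significant_loci"] = significant

    # pooled-class labels per locus, reused for the multi-locus stages
    class_labels = {
        locus: [r.genotypes[0] for r in singles[locus]["pooled_table"].rows]
        for locus in significant
        if "pooled_table" in singles[locus]
    }

    pairs: dict = {}
    for l1, l2 in itertools.combinations(sorted(class_labels), 2):
        try:
            table = cross_tabulate(
                cohort,
                assignment.affected_ids,
                assignment.unaffected_ids,
                [l1, l2],
                class_labels,
            )
            res = multilocus_association(table, family_size=config.pair_family_size)
        except ValueError as exc:
            pairs[(l1, l2)] = {"error": str(exc)}
            continue
        pairs[(l1, l2)] = {
            "table": table,
            "association": res,
            "risks": multilocus_risks(table, pop_aff, pop_total),
        }
        association_rows.append(_association_row(res))
    results["pairs"] = pairs

    triple = None
    if len(class_labels) >= 3:
        combo = sorted(class_labels)[:3]
        try:
            table = cross_tabulate(
                cohort,
                assignment.affected_ids,
                assignment.unaffected_ids,
                combo,
                class_labels,
            )
            res = multilocus_association(table, family_size=1)
            triple = {
                "table": table,
                "association": res,
                "risks": multilocus_risks(table, pop_aff, pop_total),
            }
            association_rows.append(_association_row(res))
        except ValueError as exc:
            triple = {"error": str(exc)}
    results["triple"] = triple

    # write machine-readable outputs
    pd.DataFrame(association_rows).to_csv(out / "associations.csv", index=False)
    risk_frames = []
    for locus in significant:
        frame = _risk_frame(singles[locus]["risks"])
        frame.insert(0, "loci", locus)
        risk_frames.append(frame)
    for key, entry in pairs.items():
        if "risks" in entry:
            frame = _risk_frame(entry["risks"])
            frame.insert(0, "loci", "+".join(key))
            risk_frames.append(frame)
    if triple and "risks" in triple:
        frame = _risk_frame(triple["risks"])
        frame.insert(0, "loci", "+".join(triple["table"].loci))
        risk_frames.append(frame)
    if risk_frames:
        pd.concat(risk_frames, ignore_index=True).to_csv(
            out / "risks.csv", index=False
        )

    with open(out / "report.txt", "w") as fh:
        fh.write(format_report(results))
    return results


def format_report(results: dict) -> str:
    """Human-readable multi-stage summary."""
    lines: list[str] = []
    push = lines.append
    push("Irish Wolfhound DCM/AF multi-locus association report")
    push("=" * 54)
    summary = results["phenotype"]["af_dcm"]
    push(
        f"DCM cases: {summary.n_dcm}; with AF: {summary.n_dcm_and_af} "
        f"({summary.pct_dcm_with_af:.1f}%); simultaneous: {summary.n_simultaneous}; "
        f"AF only: {summary.n_af_only}"
    )
    if summary.t_statistic is not None:
        push(
            f"AF-lag vs AF-duration t = {summary.t_statistic:.2f} "
            f"(p = {summary.p_value:.2f})"
        )
    thresholds = results["phenotype"]["onset_thresholds"]
    push(f"Onset thresholds (quantile rule): {thresholds}")
    pop_aff, pop_total = results["population"]
    push(
        f"Classified population: {pop_aff} affected / {pop_total} "
        f"({pop_aff / pop_total:.2f} risk)"
    )
    push("")
    push("Per-locus results")
    push("-" * 54)
    for locus, entry in results["singles"].items():
        if "error" in entry:
            push(f"{locus}: {entry['error']}")
            continue
        res = entry["association"]
        push(
            f"{locus}: model {entry['model']}, test {res.test_type}, "
            f"chi2 = {res.chi2:.2f} (df {res.df}), corrected p = {res.p_corrected:.4g}"
        )
        for est in entry["risks"]:
            ci = (
                f"{est.ci_low:.2f} to {est.ci_high:.2f}"
                if est.ci_low is not None
                else "undefined"
            )
            flag = " *" if est.significant else ""
            push(
                f"    {est.label}: risk {est.risk:.2f} ({est.affected}/{est.total}), "
                f"RR {est.rr:.2f} ({ci}){flag}"
            )
    push("")
    push("Multi-locus results")
    push("-" * 54)
    for key, entry in results.get("pairs", {}).items():
        if "error" in entry:
            push(f"{'+'.join(key)}: {entry['error']}")
            continue
        res = entry["association"]
        push(
            f"{'+'.join(key)}: chi2 = {res.chi2:.2f} (df {res.df}), "
            f"corrected p = {res.p_corrected:.4g}"
        )
    triple = results.get("triple")
    if triple and "association" in triple:
        res = triple["association"]
        push(
            f"{'+'.join(res.loci)}: chi2 = {res.chi2:.2f} (df {res.df}), "
            f"p = {res.p_raw:.3g}"
        )
        for est in triple["risks"]:
            ci = (
                f"{est.ci_low:.2f} to {est.ci_high:.2f}"
                if est.ci_low is not None
                else "undefined"
            )
            flag = " *" if est.significant else ""
            push(
                f"    {est.label}: risk {est.risk:.2f} ({est.affected}/{est.total}), "
                f"RR {est.rr:.2f} ({ci}){flag}"
            )
    push("")
    return "\n".join(lines)
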