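# Methods

This note records the statistical procedures the package implements, the
assumptions behind the synthetic-data generator, and the design choices
made where the published description left the construction open.

## Phenotype definitions and grouping

A dog is **affected** the moment it carries a DCM or AF diagnosis at any
heart screening, at any age — AF is treated as a precursor stage of the
same disease process, not a separate phenotype. A dog is **unaffected**
only after a clean screening strictly past a sex-specific age threshold
(defaults 6.5 y male / 8.5 y female, stored in `GroupingPolicy`, never
hard-coded: the stricter 90 % variant is a config change). Every other
dog is excluded with exactly one reason, assigned in the fixed
precedence order `unknown_age` → `died_before_threshold` →
`under_threshold` → `not_tested_since_threshold`, so the three sets
partition the cohort.

The threshold itself comes from `onset_quantile_threshold`: onset ages
are binned (default 0.5 y), and the threshold is the smallest bin upper
edge by which the cumulative share of ever-affected dogs reaches the
quantile (default 0.8). It is monotone in the quantile by construction.

Two schema notes. The cohort CSV carries `last_known_age_years` (the
dog's age at data freeze) in addition to the screening history; without
it, a living dog whose last test predates the threshold cannot be told
apart from one that simply is not old enough. It also carries
`birth_known`, backing the `unknown_age` exclusion. Ages are decimal
years throughout; no dates are stored.

The AF-lag t-test compares, for dually diagnosed dogs, first-DCM age
minus first-AF age against the AF-only dogs' time from first AF to last
screening. Simultaneous diagnoses contribute zero lags and are included
by default (`include_simultaneous=False` drops them). t-tests are
classical pooled-variance Student tests; Welch is an option flag
everywhere a t-test appears. The sex-proportion test is a plain 2×2
Pearson χ² without continuity correction.

## Penetrance models and model selection

Each locus is oriented so that a/a is the homozygote with the *lower
observed risk* (ties broken alphabetically); the four models then give
penetrance vectors in (f₀, γ) as tabulated in the README, each
component capped at 1 before expected counts are formed (the additive
model's 2f₀γ can exceed 1). Expected affected count per genotype class
is penetrance × class total; the fit minimises the Pearson χ²
Σ(O−E)²/E over the non-empty classes. Empty classes are skipped rather
than merged; if the heterozygote class is empty, dominant and recessive
collapse onto each other and the fixed tie order (multiplicative >
additive > dominant > recessive) decides.

The minimisation runs a vectorised coarse grid (f₀ in (0, 1] step
0.005 × γ in [0.1, 10] step 0.02) to locate the basin, then a bounded
Nelder–Mead polish (f₀ ∈ [10⁻⁶, 1], γ ∈ [0.01, 50]) to refine it. Both
stages are deterministic; the surfaces involved are smooth in each
coordinate, and on noiseless model-surface tables the minimised χ²
reaches 0 to 10⁻⁶. γ is allowed below 1 during fitting — the risk
orientation already fixes a/a as least risky, so the optimum sits at
γ ≥ 1 in practice, and constraining it would create boundary artifacts.

The winning model routes the locus to its association test:
multiplicative → allelic, additive → Cochran–Armitage trend (scores
0, 1, 2), dominant → pooled a/A+A/A vs a/a, recessive → pooled
a/a+a/A vs A/A.

## The association statistic

Expected affected counts per category are the unaffected group's
category proportions scaled to the affected total:
E_i = (u_i/Σu)·Σa, so ΣE = Σa exactly. The reported statistic is the
goodness-of-fit χ² of the observed affected counts against these
expected counts. Categories with E = 0 contribute nothing to the sum
but keep their place in df = k − 1; on the three-locus table this rule
gives χ² = 41.09 on 7 df (upper tail 7.8×10⁻⁷), and it is the only
zero-cell convention consistent with that pair of values, which is why
it is the default.

This construction is **not** the conventional 2×k contingency χ², and
it treats the control-derived proportions as known. Under the null it
is therefore anti-conservative: at balanced 500/500 sampling the
statistic is roughly twice the contingency χ², and the measured null
rejection rate at α = 0.05 is ≈ 16 % rather than 5 %. The package keeps
the construction as the default because it is the study's method and
reproduces every printed statistic; the conventional contingency test
sits behind `contingency=True` and is the variant whose type-I error
calibrates at the nominal rate (measured 4.8 % over 1,000 null
replicates). Both facts are asserted in the test suite.

Bonferroni correction is min(1, p × family size); the family size is
caller-supplied (5 for the single-locus family, 3 for the pairs).

## Relative risks

Genotype risk is affected/total. The relative risk divides it by the
*whole classified population's* risk (72/95 in the study fixtures), and
the 95 % CI uses the log method, exp(ln RR ∓ z·√(1/a − 1/n + 1/A − 1/N))
with z = Φ⁻¹(0.975) = 1.959964, treating the genotype subset and the
population as independent samples. The population containing the subset
makes this non-standard, but it is exactly the construction that
reproduces every printed interval; a disjoint-complement reference is
available behind `disjoint_reference=True`. Rows with zero affected
dogs report RR = 0 with an undefined CI, flagged non-significant — no
convention for that case is published.

Pooling merges the heterozygote with the like-penetrance homozygote
(the higher-risk one under dominance, the lower-risk one under
recessivity) or absorbs any homozygote with fewer than `min_count`
(default 5) dogs into the heterozygote class; counts are conserved
exactly. Multi-locus tables take one row per combination of pooled
classes, ordered low-risk first within each locus; dogs missing a call
at any involved locus are excluded from that table only.

## Reconstructed study tables

The publication prints, for every genotype (combination), the risk to
2 dp and the total count. `study_fixtures` recovers affected =
round(risk × total) and checks that every recovered count re-rounds to
the printed risk — it does, for all 31 rows, which validates the
reconstruction. These tables drive the regression tests and the
acceptance script; the population reference is 72/95 (risk 0.76), and
the headline phenotype proportions (29/36 = 80.6 % of DCM cases with
AF) are carried as counts.

## The synthetic cohort generator

The generator reproduces the structure the analysis assumes, not any
particular dataset:

* **Genotypes** — independent loci, HWE at the configured risk-allele
  frequency. Defaults mirror the five typed SNPs at the study's allele
  frequencies with the model kinds the analysis selected and modest
  effects (f₀ = 0.06, γ between 1.3 and 2.0 per locus).
* **Disease** — a lifetime indicator drawn at the combined penetrance
  of the dog's multi-locus genotype. `independent_or` (default)
  combines loci as 1 − Π(1 − p_l), bounded by construction;
  `product_capped` scales the baseline 1 − Π(1 − f₀_l) by the product
  of per-locus relative risks and caps at 1. Lifetime risk then onset
  age — not a hazard model — matches the analysis's penetrance framing.
* **Onset ages** — truncated normal on [1, study end], means 4.82 y
  (male) and 6.14 y (female) from the study; the dispersion is not
  published, and the 2.0 y default puts roughly 80 % of male onsets
  under 6.5 y and female onsets under 8.5 y, matching the study's
  cumulative-onset shape. AF onset equals DCM onset with probability
  0.586 (the study's simultaneous fraction) and otherwise precedes it
  by Uniform(0, 3] years (the study's maximum observed lead).
* **Observation** — other-cause mortality is exponential (default
  hazard 0.1/y, roughly consistent with the breed's ~7 y median
  lifespan), each dog gets a data-freeze age Uniform(0.5, study end),
  and screenings run on a fixed schedule (start 1.5 y, the earliest
  diagnosis age in the study; interval 1 y). Diagnosis flags are set at
  the first screening at or after the true onset; everything after
  death or freeze is censored. Genotype calls drop out independently at
  8 % (per-locus totals in the study ran 80–94 of 95). AF-without-DCM
  dogs arise purely from censoring — AF onset observed, DCM onset past
  the last screening — with no separate AF-only disease class.

Everything derives from one `numpy` Generator seeded from the config,
so identical configs give byte-identical cohorts. `return_truth=True`
exposes the latent onsets and disease indicators for calibration tests.
The AF–DCM ordering (0 ≤ DCM − AF ≤ lead) holds exactly on the latent
onsets; recorded diagnosis ages are quantised to the screening grid, so
on records the sharp bound is lead + interval.

What the generator does *not* emulate: pedigree structure and cryptic
relatedness, linkage disequilibrium between loci, disease mortality
(diseased dogs die only of other causes), owner-reported diagnoses
outside screenings, and any secular change in screening practice.
Passing tests therefore demonstrate the statistical machinery under the
analysis's own idealised assumptions, not robustness to those
real-data features.

`simulate_count_table` skips ages entirely: it draws case and control
genotype counts from the exact distributions implied by Bayes inversion
of HWE against the penetrance, P(g|case) ∝ P(g)f(g) and P(g|control) ∝
P(g)(1 − f(g)). One consequence matters for parameter recovery: under
retrospective sampling the per-genotype observed risk a_g/n_g is a
monotone *odds* distortion of the penetrance unless the case fraction
matches the population prevalence — at balanced 50:50 sampling a
dominant locus generated at γ = 2.5 fits at γ ≈ 2.05. The recovery
checks therefore test model-*kind* recovery on balanced tables (the
model form survives the distortion) and γ recovery on tables sampled at
the population case fraction, where the risk-based fit is consistent.

## Problem sizes

The test suite and acceptance script run at desk scale, chosen so the
Monte-Carlo standard errors are far below the asserted tolerances:
closed-form frequency checks at n = 20,000–50,000 dogs, calibration
sweeps at 25–100 seeds of 1,000–2,000 dogs or 10,000-genotype count
tables, and 1,000 null replicates for the type-I-error check. The whole
suite completes in well under a minute on one CPU.

## Known limitations

* The neutering comparison in the source material is labelled with
  t-values but described as observed/expected counts; the package
  provides the 2×2 χ² and does not attempt to reproduce those numbers.
* "Multigenic" in the published per-locus classification is treated as
  the multiplicative model — both route to the allelic test actually
  reported.
* The Chr21 alternative primer set's digest fragments sum to 423 bp
  against a 410 bp amplicon in the source tables; the validator reports
  the 13 bp discrepancy rather than silently correcting either number.
* Band-pattern calling treats fragments under 40 bp as optional (they
  routinely run off a 2 % agarose gel); sequence-level digestion
  simulation is not implemented because amplicon sequences are not
  published — definitions carry expected fragment sizes directly.
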