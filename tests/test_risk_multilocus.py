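"""Pooling, relative risks with log-method CIs, cross-tabulation, and
multi-locus combination tests."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wolfhound_dcm.cohort_io import CountRow, GenotypeCountTable
from wolfhound_dcm.phenotype_stats import assign_groups
from wolfhound_dcm.risk_multilocus import (
    PoolingRule,
    cross_tabulate,
    genotype_risk,
    multilocus_association,
    multilocus_risks,
    pool_genotypes,
    relative_risk_ci,
)
from wolfhound_dcm import study_fixtures as fx

POP = (fx.POPULATION_AFFECTED, fx.POPULATION_TOTAL)  # 72 / 95


class TestPooling:
    def test_small_count_pools_rare_homozygote_into_heterozygote(self):
        pooled = pool_genotypes(
            fx.single_locus_table("Chr1"), PoolingRule("small_count", min_count=5)
        )
        assert [(r.genotypes[0], r.affected, r.unaffected) for r in pooled.rows] == [
            ("CC", 44, 10),
            ("CT/TT", 17, 9),
        ]

    def test_recessive_pools_heterozygote_with_low_risk_homozygote(self):
        pooled = pool_genotypes(fx.single_locus_table("Chr37"), PoolingRule("recessive"))
        assert [(r.genotypes[0], r.affected, r.unaffected) for r in pooled.rows] == [
            ("AA", 23, 4),
            ("GA/GG", 48, 19),
        ]

    def test_dominant_pools_heterozygote_with_high_risk_homozygote(self):
        pooled = pool_genotypes(fx.single_locus_table("Chr21"), PoolingRule("dominant"))
        assert [(r.genotypes[0], r.affected, r.unaffected) for r in pooled.rows] == [
            ("AA", 11, 7),
            ("GA/GG", 57, 15),
        ]

    def test_none_rule_is_identity(self):
        table = fx.single_locus_table("Chr21")
        assert pool_genotypes(table, PoolingRule("none")) is table

    @pytest.mark.parametrize("locus", fx.SINGLE_LOCI)
    @pytest.mark.parametrize("mode", ["dominant", "recessive", "small_count"])
    def test_pooling_conserves_counts(self, locus, mode):
        table = fx.single_locus_table(locus)
        pooled = pool_genotypes(table, PoolingRule(mode))
        assert pooled.total_affected == table.total_affected
        assert pooled.total_unaffected == table.total_unaffected


class TestRelativeRisk:
    def test_published_chr1_cc_row(self):
        est = relative_risk_ci(44, 54, *POP)
        assert round(est.risk, 2) == 0.81
        assert round(est.rr, 2) == 1.08
        assert (round(est.ci_low, 2), round(est.ci_high, 2)) == (0.91, 1.28)
        assert not est.significant

    def test_published_headline_triple_row(self):
        est = relative_risk_ci(13, 14, *POP)
        assert round(est.rr, 2) == 1.23
        assert (round(est.ci_low, 2), round(est.ci_high, 2)) == (1.02, 1.47)
        assert est.significant

    def test_population_against_itself_is_exactly_one(self):
        est = relative_risk_ci(72, 95, *POP)
        assert est.rr == pytest.approx(1.0, abs=1e-12)

    def test_zero_affected_flagged_undefined(self):
        est = relative_risk_ci(0, 10, *POP)
        assert est.rr == 0.0
        assert est.ci_low is None and est.ci_high is None
        assert not est.significant

    def test_genotype_risk_published_values(self):
        assert round(genotype_risk(44, 54), 2) == 0.81
        assert round(genotype_risk(23, 27), 2) == 0.85
        assert genotype_risk(0, 10) == 0.0

    def test_ci_narrows_with_sample_size_at_fixed_risk(self):
        widths = []
        for scale in (1, 2, 4, 8):
            est = relative_risk_ci(10 * scale, 20 * scale, 720, 950)
            widths.append(est.ci_high - est.ci_low)
        assert widths == sorted(widths, reverse=True)

    def test_full_published_risk_table_regression(self):
        """Every printed risk, RR and CI bound across the single-locus
        pooled tables, the three pair tables and the triple table
        reproduces at 2 decimals from the reconstructed counts."""
        published = {
            ("Chr1",): [("CC", 0.81, 1.08, 0.91, 1.28), ("CT/TT", 0.65, 0.86, 0.64, 1.17)],
            ("Chr21",): [("AA", 0.61, 0.81, 0.55, 1.19), ("GA/GG", 0.79, 1.04, 0.89, 1.23)],
            ("Chr37",): [("AA", 0.85, 1.12, 0.93, 1.36), ("GA/GG", 0.72, 0.95, 0.78, 1.14)],
            ("Chr1", "Chr21"): [
                ("CC + GG/GA", 0.81, 1.07, 0.90, 1.28),
                ("CC + AA", 0.83, 1.10, 0.76, 1.60),
                ("CT/TT + GG/GA", 0.74, 0.97, 0.73, 1.30),
                ("CT/TT + AA", 0.33, 0.44, 0.14, 1.37),
            ],
            ("Chr1", "Chr37"): [
                ("CC + GG/GA", 0.79, 1.04, 0.85, 1.27),
                ("CC + AA", 0.88, 1.15, 0.93, 1.43),
                ("CT/TT + GG/GA", 0.61, 0.81, 0.55, 1.19),
                ("CT/TT + AA", 0.75, 0.99, 0.65, 1.50),
            ],
            ("Chr21", "Chr37"): [
                ("AA + GG/GA", 0.62, 0.81, 0.52, 1.27),
                ("AA + AA", 0.60, 0.79, 0.38, 1.63),
                ("GA/GG + GG/GA", 0.75, 0.99, 0.82, 1.20),
                ("GA/GG + AA", 0.89, 1.18, 0.97, 1.43),
            ],
            ("Chr1", "Chr21", "Chr37"): [
                ("TT/CT + AA + AA", 0.50, 0.66, 0.16, 2.65),
                ("TT/CT + AA + GG/GA", 0.25, 0.33, 0.06, 1.81),
                ("TT/CT + GA/GG + AA", 0.80, 1.06, 0.67, 1.66),
                ("TT/CT + GA/GG + GG/GA", 0.73, 0.97, 0.70, 1.34),
                ("CC + AA + AA", 0.50, 0.66, 0.16, 2.65),
                ("CC + AA + GG/GA", 1.00, 1.32, 1.18, 1.48),
                ("CC + GA/GG + AA", 0.93, 1.23, 1.02, 1.47),
                ("CC + GA/GG + GG/GA", 0.76, 1.01, 0.81, 1.26),
            ],
        }
        tables = {
            ("Chr1",): fx.single_locus_table("Chr1", pooled=True),
            ("Chr21",): fx.single_locus_table("Chr21", pooled=True),
            ("Chr37",): fx.single_locus_table("Chr37", pooled=True),
            ("Chr1", "Chr21"): fx.pair_table("Chr1", "Chr21"),
            ("Chr1", "Chr37"): fx.pair_table("Chr1", "Chr37"),
            ("Chr21", "Chr37"): fx.pair_table("Chr21", "Chr37"),
            ("Chr1", "Chr21", "Chr37"): fx.triple_table(),
        }
        for loci, rows in published.items():
            estimates = {e.label: e for e in multilocus_risks(tables[loci], *POP)}
            for label, risk, rr, lo, hi in rows:
                est = estimates[label]
                assert round(est.risk, 2) == pytest.approx(risk), (loci, label)
                assert round(est.rr, 2) == pytest.approx(rr), (loci, label)
                assert round(est.ci_low, 2) == pytest.approx(lo), (loci, label)
                assert round(est.ci_high, 2) == pytest.approx(hi), (loci, label)


class TestCrossTabulate:
    CLASSES = {
        "Chr21": ["AA", "GA/GG"],
        "Chr37": ["AA", "GA/GG"],
        "Chr1": ["CC", "CT/TT"],
    }

    def test_two_loci_give_four_rows(self, default_cohort):
        groups = assign_groups(default_cohort)
        table = cross_tabulate(
            default_cohort,
            groups.affected_ids,
            groups.unaffected_ids,
            ["Chr21", "Chr37"],
            self.CLASSES,
        )
        assert len(table.rows) == 4
        assert table.loci == ("Chr21", "Chr37")

    def test_counts_equal_brute_force_enumeration(self, default_cohort):
        groups = assign_groups(default_cohort)
        loci = ["Chr1", "Chr21"]
        table = cross_tabulate(
            default_cohort,
            groups.affected_ids,
            groups.unaffected_ids,
            loci,
            self.CLASSES,
        )

        def classify(call, labels):
            key = "".join(sorted(call.label))
            for label in labels:
                members = {"".join(sorted(g)) for g in label.split("/")}
                if key in members:
                    return label
            return None

        brute = {}
        for dog in default_cohort:
            if dog.dog_id in groups.affected_ids:
                slot = 0
            elif dog.dog_id in groups.unaffected_ids:
                slot = 1
            else:
                continue
            calls = [dog.genotype_at(l) for l in loci]
            if any(c is None for c in calls):
                continue
            combo = tuple(
                classify(c, self.CLASSES[l]) for c, l in zip(calls, loci)
            )
            brute.setdefault(combo, [0, 0])[slot] += 1
        for row in table.rows:
            assert [row.affected, row.unaffected] == brute.get(
                row.genotypes, [0, 0]
            )
        assert table.grand_total == sum(a + u for a, u in brute.values())

    def test_disjoint_groups_rejected(self, default_cohort):
        with pytest.raises(ValueError):
            cross_tabulate(
                default_cohort, set(), set(), ["Chr21", "Chr37"], self.CLASSES
            )


class TestMultilocusAssociation:
    @pytest.mark.parametrize(
        "pair, chi2",
        [
            (("Chr1", "Chr21"), 14.16),
            (("Chr1", "Chr37"), 15.56),
            (("Chr21", "Chr37"), 24.55),
        ],
    )
    def test_pair_tables_reproduce_published_chi2(self, pair, chi2):
        res = multilocus_association(fx.pair_table(*pair), family_size=3)
        assert res.chi2 == pytest.approx(chi2, abs=0.01)
        assert res.df == 3

    def test_triple_table_reproduces_published_chi2_and_p(self):
        res = multilocus_association(fx.triple_table())
        assert res.chi2 == pytest.approx(41.09, abs=0.01)
        assert res.df == 7
        assert res.p_raw == pytest.approx(7.8e-7, rel=0.01)

    def test_triple_fixture_affected_counts(self):
        assert [r.affected for r in fx.triple_table().rows] == [1, 1, 4, 11, 1, 4, 13, 26]

    def test_headline_combination_flagged_significant(self):
        estimates = multilocus_risks(fx.triple_table(), *POP)
        flagged = {e.label for e in estimates if e.significant}
        assert "CC + GA/GG + AA" in flagged

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, derandomize=True)
    def test_expected_total_conserved_on_random_tables(self, seed):
        import numpy as np

        from wolfhound_dcm.association_tests import expected_affected

        rng = np.random.default_rng(seed)
        k = rng.integers(2, 9)
        affected = rng.integers(0, 30, size=k)
        unaffected = rng.integers(0, 30, size=k)
        if affected.sum() == 0 or unaffected.sum() == 0:
            return
        expected = expected_affected(affected, unaffected)
        assert expected.sum() == pytest.approx(affected.sum())
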