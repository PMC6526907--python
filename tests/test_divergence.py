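"""Codon stripping, lineage-polarized counting, pooling and permutation tests."""

import numpy as np
import pytest

from fasterx.divergence import (
    BranchCounts,
    CodonAlignmentTriple,
    bootstrap_genes,
    contrast_report,
    lineage_counts,
    percent_increase,
    pool_dnds,
    randomization_test,
    strip_untranslatable_codons,
)
from fasterx.synth import CodonSimSpec, gen_codon_alignments


def triple(i1, i2, og, cls="A", gene="g"):
    return CodonAlignmentTriple(gene, i1, i2, og, cls)


class TestStrip:
    def test_bad_codon_removed_from_all_three(self):
        t = triple("ATGANAGGG", "ATGAAAGGG", "ATGAAAGGG")
        out = strip_untranslatable_codons(t)
        assert out.ingroup1 == out.ingroup2 == out.outgroup == "ATGGGG"

    def test_clean_alignment_unchanged(self):
        t = triple("ATGGGA", "ATGGGA", "ATGGGA")
        assert strip_untranslatable_codons(t) is t

    def test_gap_and_iupac_also_stripped(self):
        t = triple("ATG--AGGG", "ATGAAAGGG", "ATGARAGGG")
        out = strip_untranslatable_codons(t)
        assert out.ingroup1 == "ATGGGG"

    def test_order_independence(self):
        # set semantics: stripping twice equals stripping once
        t = triple("ANAGGGTTT", "AAAGNGTTT", "AAAGGGTTT")
        once = strip_untranslatable_codons(t)
        twice = strip_untranslatable_codons(once)
        assert once.ingroup1 == twice.ingroup1 == "TTT"

    def test_all_bad_returns_none(self, caplog):
        t = triple("ANA", "AAA", "AAA")
        assert strip_untranslatable_codons(t) is None


class TestLineageCounts:
    def test_identical_sequences_give_zero(self):
        c = lineage_counts(triple("ATGGGAAAA", "ATGGGAAAA", "ATGGGAAAA"))
        assert c.nd == {"ingroup1": 0, "ingroup2": 0}
        assert c.sd == {"ingroup1": 0, "ingroup2": 0}
        assert c.s_sites > 0 and c.n_sites > 0

    def test_synonymous_change_polarized_to_ingroup2(self):
        # ingroup2 carries GGA where ingroup1 and outgroup carry GGG
        c = lineage_counts(triple("GGG", "GGA", "GGG"))
        assert c.sd["ingroup2"] == pytest.approx(1.0)
        assert c.sd["ingroup1"] == 0 and c.nd["ingroup1"] == 0
        assert c.nd["ingroup2"] == 0

    def test_shared_derived_state_not_counted_on_ingroup_branches(self):
        c = lineage_counts(triple("GGA", "GGA", "GGG"))
        assert sum(c.sd.values()) + sum(c.nd.values()) == 0

    def test_unpolarizable_column_fully_excluded(self):
        base = lineage_counts(triple("AAA", "AAA", "AAA"))
        with_bad = lineage_counts(triple("AAAGGG", "AAAGGA", "AAAGGC"))
        # GGC matches neither GGG nor GGA: excluded from sites too
        assert with_bad.s_sites == pytest.approx(base.s_sites)

    def test_simulated_single_branch_substitutions_polarize_correctly(self):
        spec = CodonSimSpec(
            n_genes_per_class=100, codons_per_gene=100,
            branch_ds={"ingroup1": 0.03, "ingroup2": 0.0, "outgroup": 0.0},
            omega=0.2, seed=8,
        )
        triples, truth = gen_codon_alignments(spec)
        genes = [lineage_counts(t) for t in triples]
        on1 = sum(g.sd["ingroup1"] + g.nd["ingroup1"] for g in genes)
        on2 = sum(g.sd["ingroup2"] + g.nd["ingroup2"] for g in genes)
        assert on1 / (on1 + on2) >= 0.95


class TestPoolDnds:
    def test_single_gene_arithmetic(self):
        g = BranchCounts("g", "A", {"ingroup1": 1}, {"ingroup1": 2}, 1000.0, 400.0)
        s = pool_dnds([g], "ingroup1")
        assert (s.dn, s.ds, s.omega) == (0.001, 0.005, pytest.approx(0.2))

    def test_pooling_invariant_to_order_and_splitting(self):
        g1 = BranchCounts("a", "A", {"ingroup1": 2}, {"ingroup1": 4}, 600.0, 300.0)
        g2 = BranchCounts("b", "A", {"ingroup1": 1}, {"ingroup1": 1}, 400.0, 100.0)
        merged = BranchCounts("ab", "A", {"ingroup1": 3}, {"ingroup1": 5}, 1000.0, 400.0)
        s12 = pool_dnds([g1, g2], "ingroup1")
        s21 = pool_dnds([g2, g1], "ingroup1")
        sm = pool_dnds([merged], "ingroup1")
        assert s12.dn == s21.dn == sm.dn
        assert s12.ds == s21.ds == sm.ds

    def test_omega_is_ratio_of_pooled_rates(self):
        g1 = BranchCounts("a", "A", {"ingroup1": 2}, {"ingroup1": 4}, 600.0, 300.0)
        g2 = BranchCounts("b", "A", {"ingroup1": 1}, {"ingroup1": 1}, 400.0, 100.0)
        s = pool_dnds([g1, g2], "ingroup1")
        assert s.omega == pytest.approx(s.dn / s.ds)

    def test_zero_synonymous_reports_missing_omega(self):
        g = BranchCounts("g", "A", {"ingroup1": 1}, {"ingroup1": 0}, 1000.0, 400.0)
        assert pool_dnds([g], "ingroup1").omega is None


class TestBootstrap:
    def test_identical_genes_zero_width_ci(self):
        genes = [
            BranchCounts(f"g{i}", "A", {"ingroup1": 1}, {"ingroup1": 2}, 500.0, 200.0)
            for i in range(10)
        ]
        s = bootstrap_genes(genes, "ingroup1", n_boot=100, seed=0)
        assert s.ci["omega"][0] == pytest.approx(s.ci["omega"][1])

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(5)
        genes = [
            BranchCounts(
                f"g{i}", "A",
                {"ingroup1": int(rng.integers(0, 5))},
                {"ingroup1": int(rng.integers(1, 9))}, 500.0, 200.0,
            )
            for i in range(30)
        ]
        a = bootstrap_genes(genes, "ingroup1", n_boot=200, seed=42)
        b = bootstrap_genes(genes, "ingroup1", n_boot=200, seed=42)
        assert a.ci == b.ci

    def test_omega_ci_coverage_near_nominal(self):
        """~95% of CIs should cover the generating omega (count-model
        replicates, binomial slack)."""
        rng = np.random.default_rng(7)
        omega_true = 0.5
        cover = 0
        n_rep = 200
        for _ in range(n_rep):
            genes = [
                BranchCounts(
                    f"g{i}", "A",
                    {"ingroup1": int(rng.poisson(2.0 * omega_true))},
                    {"ingroup1": int(rng.poisson(2.0))},
                    900.0, 300.0,  # equal per-site opportunity: omega = ratio
                )
                for i in range(60)
            ]
            # per-site rates: dn = sum(nd)/900n, ds = sum(sd)/300n -> omega
            # true pooled omega: (2*0.5/900)/(2/300) = 1/6
            s = bootstrap_genes(genes, "ingroup1", n_boot=300,
                                seed=int(rng.integers(2**31)))
            lo, hi = s.ci["omega"]
            cover += lo <= (2 * omega_true / 900) / (2 / 300) <= hi
        assert cover / n_rep == pytest.approx(0.95, abs=0.04)


def _two_class_genes(rng, n_per_class, omega_x, omega_a, lam_s=2.0):
    genes = []
    for cls, om in (("X", omega_x), ("A", omega_a)):
        for i in range(n_per_class):
            sd = int(rng.poisson(lam_s))
            nd = int(rng.poisson(lam_s * om))
            genes.append(
                BranchCounts(
                    f"{cls}{i}", cls,
                    {"ingroup1": nd, "ingroup2": nd},
                    {"ingroup1": sd, "ingroup2": sd},
                    300.0, 300.0,
                )
            )
    return genes


class TestRandomizationTest:
    def test_constant_statistic_gives_p_one(self):
        rng = np.random.default_rng(3)
        genes = [
            BranchCounts(
                f"g{i}", "X" if i % 2 else "A",
                {"ingroup1": 1, "ingroup2": 1},
                {"ingroup1": 2, "ingroup2": 2}, 300.0, 300.0,
            )
            for i in range(40)
        ]
        res = randomization_test(genes, n_perm=200, seed=1)
        assert res.p_two_tailed == pytest.approx(1.0)

    def test_detects_large_class_difference(self):
        rng = np.random.default_rng(9)
        genes = _two_class_genes(rng, 300, omega_x=0.6, omega_a=0.1)
        res = randomization_test(genes, statistic="omega_diff", n_perm=500, seed=2)
        assert res.p_two_tailed < 0.01
        assert res.statistic_observed > 0

    def test_species_swap_grouping(self):
        rng = np.random.default_rng(11)
        genes = []
        for i in range(200):
            genes.append(
                BranchCounts(
                    f"g{i}", "A",
                    {"ingroup1": int(rng.poisson(3.0)), "ingroup2": int(rng.poisson(1.0))},
                    {"ingroup1": int(rng.poisson(2.0)), "ingroup2": int(rng.poisson(2.0))},
                    300.0, 300.0,
                )
            )
        res = randomization_test(
            genes, grouping="species-within-class", statistic="omega_diff",
            n_perm=500, seed=3,
        )
        assert res.p_two_tailed < 0.01

    def test_single_class_input_rejected(self):
        genes = [
            BranchCounts(f"g{i}", "X", {"ingroup1": 1, "ingroup2": 1},
                         {"ingroup1": 1, "ingroup2": 1}, 100.0, 100.0)
            for i in range(10)
        ]
        with pytest.raises(ValueError):
            randomization_test(genes, n_perm=50, seed=0)


class TestContrasts:
    def test_published_style_percent_increases(self):
        assert percent_increase(0.177, 0.131) == pytest.approx(35.0, abs=0.2)
        assert percent_increase(0.131, 0.114) == pytest.approx(15.0, abs=0.1)
        assert 0.177 / 0.131 == pytest.approx(1.35, abs=0.005)

    def test_equal_inputs_zero_increase(self):
        assert percent_increase(0.2, 0.2) == 0.0

    def test_contrast_report_shape(self):
        from fasterx.divergence import SubstitutionSummary

        summaries = {
            (lin, cls): SubstitutionSummary(lin, cls, dn, ds, dn / ds, 10)
            for (lin, cls), (dn, ds) in {
                ("ingroup1", "X"): (0.0010, 0.0059),
                ("ingroup1", "A"): (0.0012, 0.0093),
                ("ingroup2", "X"): (0.0008, 0.0060),
                ("ingroup2", "A"): (0.0010, 0.0083),
            }.items()
        }
        rep = contrast_report(summaries)
        row = rep[rep["contrast"] == "ingroup1:X_vs_A"].iloc[0]
        assert row["ds_ratio"] == pytest.approx(0.0059 / 0.0093)
        assert len(rep) == 4
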