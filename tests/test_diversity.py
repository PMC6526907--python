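"""Nei pi, subalignment construction, CV, ratio pairing and group tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fasterx.diversity import (
    PopulationLocusAlignment,
    bootstrap_pi,
    build_subalignments,
    block_pi,
    nei_pi,
    pair_pix_pia,
    per_scaffold_pi,
    population_ratio_test,
    scaffold_cv,
    species_ratio_test,
)


def _locus(pop, lid, scaf, pos, cls, seqs, n_ind=None):
    n = len(seqs)
    names = [f"{pop}_ind{i//2:02d}_a{i%2+1}" for i in range(n)]
    return PopulationLocusAlignment(pop, lid, scaf, pos, cls, names, seqs)


class TestNeiPi:
    def test_identical_sequences_zero(self):
        assert nei_pi(["ACGT" * 10] * 4).pi == 0.0

    def test_hand_enumerated_biallelic_site(self):
        # 4 sequences, one site with 2/2 split: 4 of 6 pairs differ
        seqs = ["A" + "C" * 99, "A" + "C" * 99, "G" + "C" * 99, "G" + "C" * 99]
        assert nei_pi(seqs).pi == pytest.approx((4 / 6) / 100)

    def test_matches_bruteforce_hamming_oracle(self, rng):
        alphabet = np.array(list("ACGTN-"))
        for _ in range(50):
            n = rng.integers(2, 8)
            L = rng.integers(5, 60)
            seqs = ["".join(alphabet[rng.integers(0, 6, L)]) for _ in range(n)]
            got = nei_pi(seqs).pi
            props = []
            for a, b in itertools.combinations(seqs, 2):
                comp = [
                    (x, y) for x, y in zip(a, b) if x in "ACGT" and y in "ACGT"
                ]
                if comp:
                    props.append(sum(x != y for x, y in comp) / len(comp))
            expect = float(np.mean(props)) if props else None
            if expect is None:
                assert got is None
            else:
                assert got == pytest.approx(expect)

    def test_invariant_to_sequence_order_and_phase(self, rng):
        seqs = ["ACGTAC", "ACGAAC", "TCGTAC", "ACGTTC"]
        base = nei_pi(seqs).pi
        assert nei_pi(seqs[::-1]).pi == pytest.approx(base)
        assert nei_pi([seqs[1], seqs[0], seqs[3], seqs[2]]).pi == pytest.approx(base)

    def test_concatenation_is_site_weighted_mean(self):
        a = ["ACGT", "ACGA", "ACGT"]
        b = ["GGGGGGGG", "GGGGGGGT", "GGGGGGGG"]
        cat = [x + y for x, y in zip(a, b)]
        pa, pb, pc = nei_pi(a).pi, nei_pi(b).pi, nei_pi(cat).pi
        assert pc == pytest.approx((4 * pa + 8 * pb) / 12)

    def test_single_sequence_rejected(self):
        with pytest.raises(ValueError):
            nei_pi(["ACGT"])


class TestBuildSubalignments:
    def test_universal_length_anchored_to_thinnest_x_population(self):
        # population B has the smallest X total: 136,432 bp -> L = 9,095
        def xloci(pop, lens):
            return [
                _locus(pop, f"x{i}", f"scf{i}", 0, "X", ["A" * L] * 10)
                for i, L in enumerate(lens)
            ]

        loci = (
            xloci("A", [100_000, 60_000])
            + xloci("B", [100_000, 36_432])
            + [_locus(p, "a0", "scfA", 0, "A", ["C" * 200_000] * 10) for p in "AB"]
        )
        out = build_subalignments(loci, target_min_blocks=15)
        L = out[("B", "X")].block_length
        assert L == 136_432 // 15 == 9095
        assert len(out[("B", "X")].blocks) == 15
        assert len(out[("A", "X")].blocks) == 160_000 // 9095
        assert all(b.shape[1] == L for b in out[("A", "A")].blocks)

    def test_exact_multiple_discards_nothing(self):
        loci = [
            _locus("P", "x0", "s", 0, "X", ["A" * 3000] * 6),
            _locus("P", "a0", "s", 0, "A", ["C" * 600] * 6),
        ]
        out = build_subalignments(loci, target_min_blocks=3)
        assert out[("P", "X")].block_length == 1000
        assert len(out[("P", "X")].blocks) == 3

    @given(st.lists(st.integers(50, 500), min_size=2, max_size=8))
    @settings(max_examples=30, deadline=None)
    def test_block_count_is_floor_total_over_length(self, lens):
        loci = [
            _locus("P", f"x{i}", f"s{i}", 0, "X", ["A" * L] * 4)
            for i, L in enumerate(lens)
        ]
        out = build_subalignments(loci, target_min_blocks=2)
        total = sum(lens)
        L = total // 2
        assert len(out[("P", "X")].blocks) == total // L

    def test_missing_individuals_become_gap_rows(self):
        l1 = _locus("P", "x0", "s0", 0, "X", ["AAAA"] * 4)
        l2 = PopulationLocusAlignment(
            "P", "x1", "s1", 0, "X",
            ["P_ind05_a1", "P_ind05_a2"], ["CCCC", "CCCC"],
        )
        out = build_subalignments([l1, l2], target_min_blocks=2)
        block = out[("P", "X")].blocks[0]
        assert block.shape[0] == 6  # union of rows
        # ind05 is absent from locus x0, so its rows are gaps in block 0
        assert bytes(block[4]).decode() == "----"


class TestBootstrapPi:
    def test_identical_blocks_zero_width(self):
        out = bootstrap_pi(np.full(10, 0.004), n_boot=200, seed=1)
        assert out["ci_low"] == pytest.approx(out["ci_high"], rel=1e-12)
        assert out["ci_low"] == pytest.approx(0.004, rel=1e-12)

    def test_seed_stability(self):
        vals = np.random.default_rng(2).gamma(2, 0.001, 30)
        a = bootstrap_pi(vals, n_boot=500, seed=9)
        b = bootstrap_pi(vals, n_boot=500, seed=9)
        assert a == b

    def test_coverage_near_nominal_on_known_mean(self):
        rng = np.random.default_rng(4)
        true_mean = 2.0 * 0.002  # gamma(shape=2, scale=0.002)
        cover = 0
        for _ in range(200):
            vals = rng.gamma(2.0, 0.002, 40)
            out = bootstrap_pi(vals, n_boot=400, seed=int(rng.integers(2**31)))
            cover += out["ci_low"] <= true_mean <= out["ci_high"]
        assert cover / 200 == pytest.approx(0.95, abs=0.04)


class TestScaffoldCV:
    def test_hand_example(self):
        assert scaffold_cv([1, 2, 3], n_boot=50, seed=0)["cv"] == pytest.approx(0.5)

    def test_constant_values_zero(self):
        assert scaffold_cv([2, 2, 2, 2], n_boot=50, seed=0)["cv"] == 0.0

    @given(st.floats(0.1, 100.0))
    @settings(max_examples=30, deadline=None)
    def test_scale_invariance(self, c):
        base = scaffold_cv([1.0, 2.0, 5.0], n_boot=10, seed=1)["cv"]
        scaled = scaffold_cv([c, 2 * c, 5 * c], n_boot=10, seed=1)["cv"]
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_zero_mean_flagged(self):
        with pytest.raises(ValueError, match="undefined"):
            scaffold_cv([0.0, 0.0, 0.0])

    def test_per_scaffold_pi_requires_three_loci(self):
        loci = [
            _locus("P", f"l{i}", "scf1", i * 100, "A", ["ACGT" * 5] * 4)
            for i in range(3)
        ] + [_locus("P", "l9", "scf2", 0, "A", ["ACGT" * 5] * 4)]
        df = per_scaffold_pi(loci)
        assert set(df["scaffold_id"]) == {"scf1"}


class TestPairPixPia:
    def test_paper_scale_grouping_counts(self, rng):
        x = rng.gamma(2, 0.001, 15)
        a = rng.gamma(2, 0.0013, 150)
        df = pair_pix_pia(x, a, seed=0)
        assert len(df) == 15

    def test_equal_pi_gives_unit_ratios(self):
        df = pair_pix_pia([0.01] * 5, [0.01] * 40, seed=3)
        assert np.allclose(df["ratio"], 1.0)

    def test_zero_median_pairs_dropped(self, caplog):
        df = pair_pix_pia([0.01, 0.02], [0.0] * 10, seed=0)
        assert len(df) == 0

    def test_requires_enough_blocks(self):
        with pytest.raises(ValueError):
            pair_pix_pia([0.01], [0.01] * 5, seed=0)


def _ratio_frame(rng, effects, n_blocks=15, sd=0.08):
    rows = []
    for species, pops in effects.items():
        for pop, mean in pops.items():
            for r in rng.normal(mean, sd, n_blocks):
                rows.append({"species": species, "population": pop, "ratio": r})
    return pd.DataFrame(rows)


class TestGroupTests:
    def test_species_effect_detected(self, rng):
        df = _ratio_frame(
            rng,
            {
                "sub": {"P1": 0.57, "P2": 0.57, "P3": 0.58},
                "soc": {"Q1": 0.72, "Q2": 0.71, "Q3": 0.73},
            },
        )
        out = species_ratio_test(df)
        assert out["p_value"] < 0.05

    def test_single_population_per_species_rejected(self, rng):
        df = _ratio_frame(rng, {"sub": {"P1": 0.6}, "soc": {"Q1": 0.7}})
        with pytest.raises(ValueError, match="populations per species"):
            species_ratio_test(df)

    def test_identical_groups_f_zero_p_one(self):
        df = pd.DataFrame(
            {"population": ["P1"] * 3 + ["P2"] * 3, "ratio": [1, 2, 3, 1, 2, 3]}
        )
        out = population_ratio_test(df)
        assert out["F"] == pytest.approx(0.0)
        assert out["p_value"] == pytest.approx(1.0)

    def test_f_matches_textbook_anova_on_hand_example(self):
        groups = {"P1": [1.0, 2.0, 3.0], "P2": [2.0, 3.0, 4.0], "P3": [5.0, 6.0, 7.0]}
        df = pd.DataFrame(
            [{"population": p, "ratio": v} for p, vs in groups.items() for v in vs]
        )
        out = population_ratio_test(df)
        grand = np.mean([v for vs in groups.values() for v in vs])
        ssb = sum(3 * (np.mean(vs) - grand) ** 2 for vs in groups.values())
        ssw = sum((v - np.mean(vs)) ** 2 for vs in groups.values() for v in vs)
        f_hand = (ssb / 2) / (ssw / 6)
        assert out["F"] == pytest.approx(f_hand)
        assert out["df1"] == 2 and out["df2"] == 6

    def test_distinct_populations_get_distinct_letters(self, rng):
        df = _ratio_frame(
            rng, {"s": {"P1": 0.4, "P2": 0.4, "P3": 0.9}}, n_blocks=20, sd=0.05
        )
        out = population_ratio_test(df)
        assert out["p_value"] < 0.01
        letters = out["letters"]
        assert letters["P3"] != letters["P1"]
        assert set(letters["P1"]) & set(letters["P2"])
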