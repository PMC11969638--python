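import math

import numpy as np
import pytest

from gsped.genetic_map import BreakpointList, GenomeSpec, RecombMap, build_rec_map
from gsped.gsp import GspInvalidError, backcross_gsp, f1_gsp, f2_gsp, load_gsp, pure_gsp, random_gsp
from gsped.segregate import (FounderSlot, admixture_fraction,
                             ancestry_genotype_fractions, frame_to_samples,
                             meiosis, segments_to_frame, segregate, _recombine)

from .conftest import check_conservation
from .test_gsp import figure_example_tables


def founder_pair(genome, pops=("A", "B"), founder="f"):
    slots = [
        FounderSlot("g", 0, founder, h, pops[h - 1]) for h in (1, 2)
    ]
    return tuple(
        {c: [(0, genome.length_of(c), s)] for c in genome.chroms} for s in slots
    ), slots


def assert_complementary(g1, g2, genome):
    """The two meiosis products carry different origins at every bp."""
    for c in genome.chroms:
        s1, s2 = g1[c], g2[c]
        i = j = pos = 0
        L = genome.length_of(c)
        while pos < L:
            nxt = min(s1[i][1], s2[j][1])
            assert s1[i][2] is not s2[j][2], (c, pos)
            pos = nxt
            if s1[i][1] == nxt:
                i += 1
            if s2[j][1] == nxt:
                j += 1


class TestMeiosis:
    def test_zero_recombination_passes_haplotypes_intact(self, toy_genome):
        rec = build_rec_map(toy_genome, cM_per_Mb=0.0, spacing=1_000_000)
        pair, slots = founder_pair(toy_genome)
        out1, out2 = meiosis(pair, rec, np.random.default_rng(0))
        for gam in (out1, out2):
            for c in toy_genome.chroms:
                assert len(gam[c]) == 1  # one intact parental haplotype
        assert_complementary(out1, out2, toy_genome)

    def test_single_forced_crossover_geometry(self, toy_genome):
        pair, slots = founder_pair(toy_genome)
        L = toy_genome.length_of("1")
        mask = BreakpointList("1", start_slot=1, positions=np.array([4_000_000]))
        out1, out2 = _recombine((pair[0]["1"], pair[1]["1"]), mask, L)
        assert out1 == [(0, 4_000_000, slots[0]), (4_000_000, L, slots[1])]
        assert out2 == [(0, 4_000_000, slots[1]), (4_000_000, L, slots[0])]

    def test_products_are_complementary(self, toy_genome, toy_recmap):
        pair, _ = founder_pair(toy_genome)
        rng = np.random.default_rng(5)
        for _ in range(20):
            out1, out2 = meiosis(pair, toy_recmap, rng)
            assert_complementary(out1, out2, toy_genome)

    def test_breakpoint_rate_matches_map(self, toy_genome, toy_recmap):
        pair, _ = founder_pair(toy_genome)
        rng = np.random.default_rng(6)
        n = 3000
        switches = 0
        for _ in range(n):
            out1, _ = meiosis(pair, toy_recmap, rng)
            switches += sum(len(out1[c]) - 1 for c in toy_genome.chroms)
        expect = toy_recmap.expected_crossovers()
        se = math.sqrt(expect / n)
        assert abs(switches / n - expect) < 4 * se

    def test_genome_mismatch_rejected(self, toy_genome, toy_recmap):
        small = GenomeSpec(("1",), (1_000_000,))
        pair, _ = founder_pair(small)
        with pytest.raises(ValueError, match="chromosome"):
            meiosis(pair, toy_recmap, np.random.default_rng(0))


class TestSegregate:
    def test_worked_example_delivers_four_samples(self, toy_recmap):
        gsp = load_gsp(*figure_example_tables())
        samples, ledger = segregate(gsp, toy_recmap, n_reps=1, seed=0)
        assert len(samples) == 4
        assert len(ledger) == 8  # 4 founders x 2 haplotypes
        assert {s.node for s in samples} == {"s7"}

    def test_invalid_gsp_is_refused_with_report(self, toy_recmap):
        nodes, edges = figure_example_tables()
        nodes.loc[nodes["id"] == "s7", "n_samples"] = 3
        with pytest.raises(GspInvalidError) as err:
            segregate(load_gsp(nodes, edges), toy_recmap, n_reps=1, seed=0)
        assert {"c1", "c5"} <= err.value.report.conditions

    def test_f1_admixture_is_exactly_half(self, toy_genome, toy_recmap):
        samples, _ = segregate(f1_gsp("A", "B"), toy_recmap, n_reps=5, seed=1)
        for s in samples:
            assert admixture_fraction(s, "A", toy_genome) == 0.5

    def test_same_seed_reproduces_everything(self, toy_recmap):
        gsp = f2_gsp("A", "B")
        s1, _ = segregate(gsp, toy_recmap, n_reps=3, seed=7)
        s2, _ = segregate(gsp, toy_recmap, n_reps=3, seed=7)
        assert segments_to_frame(s1).equals(segments_to_frame(s2))

    def test_conservation_on_random_pedigrees(self, toy_genome, toy_recmap):
        rng = np.random.default_rng(11)
        for k in range(8):
            gsp = random_gsp(rng)
            samples, ledger = segregate(gsp, toy_recmap, n_reps=2, seed=k)
            check_conservation(samples, ledger, toy_genome)

    def test_segment_frame_roundtrip(self, toy_genome, toy_recmap):
        samples, ledger = segregate(f2_gsp("A", "B"), toy_recmap, n_reps=2, seed=3)
        df = segments_to_frame(samples)
        back, back_ledger = frame_to_samples(df, toy_genome)
        assert len(back) == len(samples)
        assert len(back_ledger) == len(ledger)
        assert segments_to_frame(back).equals(df)


class TestAncestryFractions:
    def test_pure_sample_is_all_one_population(self, toy_genome, toy_recmap):
        samples, _ = segregate(pure_gsp("A"), toy_recmap, n_reps=1, seed=2)
        for s in samples:
            assert admixture_fraction(s, "A", toy_genome) == 1.0
            assert ancestry_genotype_fractions(s, "A", toy_genome) == (1.0, 0.0, 0.0)

    def test_f1_triplet_is_all_heterozygous(self, toy_genome, toy_recmap):
        samples, _ = segregate(f1_gsp("A", "B"), toy_recmap, n_reps=1, seed=2)
        for s in samples:
            assert ancestry_genotype_fractions(s, "A", toy_genome) == (0.0, 1.0, 0.0)

    def test_triplet_sums_to_one_exactly(self, toy_genome, toy_recmap):
        samples, _ = segregate(backcross_gsp(2, "A", "B"), toy_recmap, n_reps=2, seed=4)
        for s in samples:
            f2, f1, f0 = ancestry_genotype_fractions(s, "A", toy_genome)
            assert f2 + f1 + f0 == pytest.approx(1.0, abs=1e-12)
            assert admixture_fraction(s, "A", toy_genome) == pytest.approx(
                f2 + f1 / 2, abs=1e-12
            )

    def test_unknown_population_warns_and_returns_zero(self, toy_genome, toy_recmap):
        samples, _ = segregate(pure_gsp("A"), toy_recmap, n_reps=1, seed=2)
        with pytest.warns(UserWarning, match="does not occur"):
            assert admixture_fraction(samples[0], "Z", toy_genome) == 0.0

    def test_bc1_mean_admixture_is_three_quarters_by_conservation(
        self, toy_genome, toy_recmap
    ):
        # all founder material ends in the samples, so the per-replicate mean
        # admixture equals the founder population fraction exactly
        samples, _ = segregate(backcross_gsp(1, "A", "B"), toy_recmap, n_reps=10, seed=5)
        qs = [admixture_fraction(s, "A", toy_genome) for s in samples]
        assert np.mean(qs) == pytest.approx(0.75, abs=1e-12)

    def test_per_locus_genotype_distribution_matches_category(self, toy_genome, toy_recmap):
        # at a mid-chromosome locus, ancestry-genotype frequencies across
        # replicates follow the category triplet (binomial 4-sigma bands)
        reps = 400
        locus = ("2", 5_000_000)
        for gsp, triplet in [
            (f2_gsp("A", "B"), (0.25, 0.5, 0.25)),
            (backcross_gsp(1, "A", "B"), (0.5, 0.5, 0.0)),
        ]:
            samples, _ = segregate(gsp, toy_recmap, n_reps=reps, seed=8)
            counts = [0, 0, 0]
            for s in samples:
                copies = 0
                for gam in s.gametes:
                    for start, end, slot in gam[locus[0]]:
                        if start <= locus[1] < end:
                            copies += slot.population == "A"
                counts[2 - copies] += 1
            n = len(samples)
            for k, p in enumerate(triplet):
                se = math.sqrt(max(p * (1 - p), 1e-9) / n)
                assert abs(counts[k] / n - p) < 4 * se + 1e-9, (gsp, k)
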