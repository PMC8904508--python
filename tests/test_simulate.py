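"""Generator ground truth: drift moments, pedigrees, damage, tracts."""

import numpy as np
import pytest

from adnakit import (
    AdmixedSampleSpec,
    AdmixtureGraph,
    CohortSpec,
    MISSING,
    SNPPanel,
    simulate_admixed_genotypes,
    simulate_frequencies,
    simulate_genotypes,
    simulate_pileup,
)
from adnakit.graph import GraphError
from adnakit.simulate import FreqTable, random_allele_calls

from conftest import E_P1MP, exact_f2_expectation


@pytest.fixture(scope="module")
def tiny_panel():
    return SNPPanel.uniform(3_000, n_chrom=2)


class TestFrequencies:
    def test_zero_drift_copies_root(self, tiny_panel):
        g = AdmixtureGraph(
            [("root", "A", 0.0), ("root", "B", 0.0), ("root", "C", 0.0)]
        )
        f = simulate_frequencies(g, tiny_panel, seed=1, keep_internal=True)
        root = f.freq("root")
        for pop in "ABC":
            np.testing.assert_array_equal(f.freq(pop), root)

    def test_admixture_is_convex_combination(self, tiny_panel):
        g = AdmixtureGraph(
            [("root", "A", 0.05), ("root", "B", 0.05), ("M", "L", 0.0)],
            {"M": ("A", "B", 0.3)},
        )
        f = simulate_frequencies(g, tiny_panel, seed=2, keep_internal=True)
        np.testing.assert_allclose(
            f.freq("M"), 0.3 * f.freq("A") + 0.7 * f.freq("B"), atol=1e-12
        )

    def test_shared_drift_expectation(self, outgroup_trio):
        # E[(o-a)(o-b)] = shared drift * E[p(1-p)] ~ 0.02 * 0.1198 = 0.0024
        _, _, f = outgroup_trio
        o, a, b = f.freq("O"), f.freq("A"), f.freq("B")
        prod = (o - a) * (o - b)
        mc_se = prod.std() / np.sqrt(len(prod))
        assert abs(prod.mean() - 0.02 * E_P1MP) < 3 * mc_se

    def test_f2_matches_path_sum(self):
        graph = AdmixtureGraph(
            [("root", "A", 0.01), ("root", "x", 0.02),
             ("x", "B", 0.015), ("x", "C", 0.005)]
        )
        panel = SNPPanel.uniform(100_000, n_chrom=10)
        f = simulate_frequencies(graph, panel, seed=9)
        for pair in (("A", "B"), ("B", "C"), ("A", "C")):
            d = (f.freq(pair[0]) - f.freq(pair[1])) ** 2
            mc_se = d.std() / np.sqrt(len(d))
            expect = exact_f2_expectation(graph, *pair)
            assert abs(d.mean() - expect) < 3 * mc_se, pair

    def test_frequencies_in_unit_interval_and_clip_counted(self, tiny_panel):
        g = AdmixtureGraph([("root", "A", 1.5)])  # forces truncation draws
        f = simulate_frequencies(g, tiny_panel, seed=3)
        assert np.all((f.freqs >= 0) & (f.freqs <= 1))
        assert f.n_clipped > 0

    def test_cyclic_graph_rejected(self):
        with pytest.raises(GraphError):
            AdmixtureGraph([("a", "b", 0.1), ("b", "a", 0.1)])

    def test_negative_drift_rejected(self):
        with pytest.raises(GraphError):
            AdmixtureGraph([("root", "A", -0.1)])

    def test_bad_alpha_rejected(self):
        with pytest.raises(GraphError):
            AdmixtureGraph(
                [("root", "A", 0.1), ("root", "B", 0.1), ("M", "L", 0.0)],
                {"M": ("A", "B", 1.5)},
            )

    def test_same_seed_bit_identical(self, tiny_panel):
        g = AdmixtureGraph([("root", "A", 0.02), ("root", "B", 0.01)])
        f1 = simulate_frequencies(g, tiny_panel, seed=7)
        f2 = simulate_frequencies(g, tiny_panel, seed=7)
        np.testing.assert_array_equal(f1.freqs, f2.freqs)


@pytest.fixture(scope="module")
def family(tiny_panel):
    g = AdmixtureGraph([("root", "P", 0.0)])
    f = simulate_frequencies(g, tiny_panel, seed=5)
    cohort = CohortSpec(
        groups={"P": 6},
        pedigree=[
            ("P0", "P1", "duplicate"),
            ("P2", "P3", "parent_offspring"),
            ("P4", "P5", "full_sib"),
        ],
    )
    return f, simulate_genotypes(f, cohort, seed=5, panel=tiny_panel)


class TestGenotypes:
    def test_fixed_frequency_fixes_genotypes(self, tiny_panel):
        f = FreqTable(["P"], np.zeros((1, len(tiny_panel))))
        gm = simulate_genotypes(f, CohortSpec(groups={"P": 3}), seed=1,
                                panel=tiny_panel)
        assert np.all(gm.values == 0)

    def test_duplicates_identical(self, family):
        _, gm = family
        np.testing.assert_array_equal(gm.row("P0"), gm.row("P1"))

    def test_parent_offspring_share_allele_everywhere(self, family):
        # Mendelian: parent hom-alt => offspring >= 1; hom-ref => <= 1
        _, gm = family
        p, o = gm.row("P2"), gm.row("P3")
        assert np.all(o[p == 2] >= 1)
        assert np.all(o[p == 0] <= 1)

    def test_mean_heterozygosity(self):
        panel = SNPPanel.uniform(50_000)
        g = AdmixtureGraph([("root", "P", 0.0)])
        f = simulate_frequencies(g, panel, seed=6)
        gm = simulate_genotypes(f, CohortSpec(groups={"P": 10}), seed=6,
                                panel=panel)
        het = (gm.values == 1).mean()
        # 2 E[p(1-p)] = 0.46/1.92 ~ 0.2396 for Beta(0.46, 0.46)
        assert abs(het - 2 * E_P1MP) < 0.01

    def test_unknown_group_raises(self, tiny_panel):
        f = FreqTable(["P"], np.full((1, len(tiny_panel)), 0.5))
        with pytest.raises(KeyError):
            simulate_genotypes(f, CohortSpec(groups={"Q": 2}), seed=1)


@pytest.fixture(scope="module")
def cohort_and_genos(tiny_panel):
    g = AdmixtureGraph([("root", "P", 0.0)])
    f = simulate_frequencies(g, tiny_panel, seed=8)
    cohort = CohortSpec(groups={"P": 2}, mean_depth=2.0)
    gm = simulate_genotypes(f, cohort, seed=8, panel=tiny_panel)
    return cohort, gm


class TestPileup:
    def test_zero_depth_empty(self, tiny_panel, cohort_and_genos):
        _, gm = cohort_and_genos
        cohort = CohortSpec(groups={"P": 2}, mean_depth=0.0)
        pile = simulate_pileup(gm, cohort, tiny_panel, seed=1)
        assert len(pile) == 0

    def test_no_damage_means_true_alleles(self, tiny_panel, cohort_and_genos):
        cohort, gm = cohort_and_genos
        pile = simulate_pileup(gm, cohort, tiny_panel, seed=2)
        idx = {(c, int(p)): i
               for i, (c, p) in enumerate(zip(tiny_panel.chrom, tiny_panel.pos))}
        site = pile.apply(
            lambda r: idx[(r["chromosome"], r["position"])], axis=1
        ).to_numpy()
        geno = np.array(
            [gm.row(i) for i in pile["individual"]]
        )[np.arange(len(pile)), site]
        is_alt = (pile["base"].to_numpy() == tiny_panel.alt[site])
        is_ref = (pile["base"].to_numpy() == tiny_panel.ref[site])
        assert np.all(is_alt | is_ref)
        assert not np.any(is_alt & (geno == 0))
        assert not np.any(is_ref & (geno == 2))

    def test_terminal_damage_rate(self):
        # C/C individuals at C/T sites: T fraction among terminal plus-strand
        # reads ~ delta; minus-strand reads stay clean
        panel = SNPPanel.uniform(20_000, alleles=("C", "T"))
        f = FreqTable(["P"], np.zeros((1, len(panel))))  # all hom-ref C/C
        cohort = CohortSpec(groups={"P": 1}, mean_depth=5.0, damage_rate=0.1)
        gm = simulate_genotypes(f, cohort, seed=3, panel=panel)
        pile = simulate_pileup(gm, cohort, panel, read_len=70, seed=3)
        terminal = (pile["read_position"] <= 5) | (
            pile["read_position"] > pile["read_length"] - 5
        )
        plus = pile[terminal & (pile["strand"] == "+")]
        minus = pile[terminal & (pile["strand"] == "-")]
        t_rate = (plus["base"] == "T").mean()
        assert abs(t_rate - 0.1) < 3 * np.sqrt(0.1 * 0.9 / len(plus))
        assert (minus["base"] == "T").sum() == 0

    def test_short_reads_rejected(self, tiny_panel, cohort_and_genos):
        cohort, gm = cohort_and_genos
        with pytest.raises(ValueError):
            simulate_pileup(gm, cohort, tiny_panel, read_len=10, seed=1)

    def test_same_seed_bit_identical(self, tiny_panel, cohort_and_genos):
        cohort, gm = cohort_and_genos
        p1 = simulate_pileup(gm, cohort, tiny_panel, seed=11)
        p2 = simulate_pileup(gm, cohort, tiny_panel, seed=11)
        assert p1.equals(p2)


@pytest.fixture(scope="module")
def sources():
    panel = SNPPanel.uniform(1_000, n_chrom=10)  # 10 x 1 Morgan
    g = AdmixtureGraph([("root", "S1", 0.05), ("root", "S2", 0.05)])
    return panel, simulate_frequencies(g, panel, seed=12)


class TestAdmixed:
    def test_alpha_one_all_source1(self, sources):
        panel, f = sources
        spec = AdmixedSampleSpec("S1", "S2", 1.0, 46, 3)
        _, hap, tracts = simulate_admixed_genotypes(spec, f, panel, seed=1)
        assert np.all(hap == 1)
        assert all(st == 1 for _, _, _, st in tracts)

    def test_tract_length_sojourn_time(self, sources):
        # source1 sojourn: 1/((1-alpha) g) Morgans
        panel, f = sources
        g_gen, alpha = 46, 0.5
        spec = AdmixedSampleSpec("S1", "S2", alpha, g_gen, 25)
        _, _, tracts = simulate_admixed_genotypes(spec, f, panel, seed=2)
        lens = np.array([e - s for _, s, e, st in tracts if st == 1])
        expect = 1 / ((1 - alpha) * g_gen)
        # truncation at chromosome ends shortens observed tracts slightly
        assert abs(lens.mean() - expect) < 0.15 * expect

    def test_doubling_g_halves_tracts(self, sources):
        panel, f = sources
        means = {}
        for g_gen in (23, 46):
            spec = AdmixedSampleSpec("S1", "S2", 0.5, g_gen, 25)
            _, _, tracts = simulate_admixed_genotypes(spec, f, panel, seed=3)
            means[g_gen] = np.mean(
                [e - s for _, s, e, st in tracts if st == 1]
            )
        assert 1.6 < means[23] / means[46] < 2.4

    def test_bad_generations_rejected(self):
        with pytest.raises(ValueError):
            AdmixedSampleSpec("S1", "S2", 0.5, 0, 3)


class TestIdealizedCalls:
    def test_heterozygote_draw_rate(self, tiny_panel):
        f = FreqTable(["P"], np.full((1, len(tiny_panel)), 0.5))
        gm = simulate_genotypes(f, CohortSpec(groups={"P": 2}), seed=4,
                                panel=tiny_panel)
        calls = random_allele_calls(gm, seed=4)
        het = gm.values == 1
        rate = calls.values[het].mean()
        assert abs(rate - 0.5) < 3 * np.sqrt(0.25 / het.sum())
        hom = gm.values != 1
        np.testing.assert_array_equal(
            calls.values[hom], (gm.values[hom] // 2).astype(np.int8)
        )
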