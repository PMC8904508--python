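"""PMR computation, baseline estimation, and kinship classification."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from adnakit import AdmixtureGraph, GenotypeMatrix, MISSING, SNPPanel
from adnakit.relatedness import (
    PMRResult,
    classify_pairs,
    estimate_baseline,
    merge_duplicates,
    pairwise_mismatch,
)
from adnakit.simulate import (
    CohortSpec,
    simulate_frequencies,
    simulate_genotypes,
    random_allele_calls,
)


def call_matrix(rows, names=None):
    vals = np.asarray(rows, dtype=np.int8)
    panel = SNPPanel.uniform(vals.shape[1])
    names = names or [f"s{i}" for i in range(vals.shape[0])]
    return GenotypeMatrix(panel, names, vals, ploidy=1)


class TestPMR:
    def test_identical_vectors_zero(self):
        calls = call_matrix([[0, 1] * 500, [0, 1] * 500])
        res, _ = pairwise_mismatch(calls, min_overlap=100)
        assert res[0].pmr == 0.0

    def test_all_different_one(self):
        calls = call_matrix([[0] * 1000, [1] * 1000])
        res, _ = pairwise_mismatch(calls, min_overlap=100)
        assert res[0].pmr == 1.0

    def test_low_overlap_reported_insufficient(self):
        a = [0] * 10 + [MISSING] * 990
        b = [0] * 1000
        calls = call_matrix([a, b])
        res, insufficient = pairwise_mismatch(calls, min_overlap=100)
        assert res == []
        assert insufficient[0][2] == 10

    def test_symmetry_and_joint_missing_irrelevant(self):
        rng = np.random.default_rng(0)
        a = rng.choice([0, 1, MISSING], size=2000).astype(np.int8)
        b = rng.choice([0, 1, MISSING], size=2000).astype(np.int8)
        both_missing = (a == MISSING) & (b == MISSING)
        res1, _ = pairwise_mismatch(call_matrix([a, b]), min_overlap=10)
        res2, _ = pairwise_mismatch(call_matrix([b, a]), min_overlap=10)
        assert res1[0].pmr == res2[0].pmr
        keep = ~both_missing
        res3, _ = pairwise_mismatch(
            call_matrix([a[keep], b[keep]]), min_overlap=10
        )
        assert res1[0].pmr == res3[0].pmr

    def test_duplicate_pair_pmr_near_half_baseline(self):
        # two independent pseudo-haploid call sets of the same individual
        panel = SNPPanel.uniform(50_000)
        g = AdmixtureGraph([("root", "P", 0.0)])
        f = simulate_frequencies(g, panel, seed=17)
        gm = simulate_genotypes(f, CohortSpec(groups={"P": 2}), seed=17,
                                panel=panel)
        lib1 = random_allele_calls(gm, seed=21, library="L1")
        lib2 = random_allele_calls(gm, seed=22, library="L2")
        dup = (lib1.values[0] != lib2.values[0]).mean()
        unrel = (lib1.values[0] != lib1.values[1]).mean()
        assert abs(dup - 0.12) < 0.01
        assert abs(unrel - 0.24) < 0.01


def make_results(pmrs, n=10_000):
    return [
        PMRResult(( f"a{i}", f"b{i}"), n, int(round(p * n)))
        for i, p in enumerate(pmrs)
    ]


class TestBaseline:
    def test_all_equal(self):
        assert estimate_baseline(make_results([0.24] * 5)) == pytest.approx(0.24)

    def test_modal_cluster_median(self):
        b = estimate_baseline(make_results([0.12, 0.24, 0.24, 0.24]))
        assert b == pytest.approx(0.24, abs=1e-3)

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            estimate_baseline(make_results([0.2, 0.3]))

    def test_simulated_cohort_baseline_matches_heterozygosity(self):
        panel = SNPPanel.uniform(20_000)
        g = AdmixtureGraph([("root", "P", 0.0)])
        f = simulate_frequencies(g, panel, seed=31)
        cohort = CohortSpec(groups={"P": 8},
                            pedigree=[("P0", "P1", "duplicate")])
        gm = simulate_genotypes(f, cohort, seed=31, panel=panel)
        calls = random_allele_calls(gm, seed=31)
        res, _ = pairwise_mismatch(calls)
        b = estimate_baseline(res)
        het = 2 * 0.46 * 0.46 / (0.92 * 1.92)
        assert abs(b - het) < 2 * np.sqrt(het * (1 - het) / 20_000)


class TestClassification:
    def test_nearest_expected_values(self):
        res = make_results([0.121, 0.17, 0.205, 0.24])
        out = classify_pairs(res, 0.24)
        assert [c for _, c, _ in out] == [
            "duplicate", "first_degree", "second_degree", "unrelated"
        ]

    def test_bad_baseline(self):
        with pytest.raises(ValueError):
            classify_pairs(make_results([0.2]), 0.0)

    def test_pedigree_recovery(self):
        panel = SNPPanel.uniform(30_000)
        g = AdmixtureGraph([("root", "P", 0.0)])
        f = simulate_frequencies(g, panel, seed=41)
        links = [
            ("P0", "P1", "parent_offspring"),
            ("P2", "P3", "parent_offspring"),
            ("P4", "P5", "full_sib"),
            ("P6", "P7", "second_degree"),
            ("P8", "P9", "second_degree"),
        ]
        cohort = CohortSpec(groups={"P": 16}, pedigree=links)
        gm = simulate_genotypes(f, cohort, seed=41, panel=panel)
        calls = random_allele_calls(gm, seed=41)
        res, _ = pairwise_mismatch(calls)
        b = estimate_baseline(res)
        classes = {pair: c for pair, c, _ in classify_pairs(res, b)}
        expected = {
            ("P0", "P1"): "first_degree", ("P2", "P3"): "first_degree",
            ("P4", "P5"): "first_degree", ("P6", "P7"): "second_degree",
            ("P8", "P9"): "second_degree",
        }
        hits = sum(classes[p] == c for p, c in expected.items())
        assert hits >= 4  # second-degree sits closest to unrelated


class TestMergeDuplicates:
    def test_single_member_group_unchanged(self):
        calls = call_matrix([[0, 1, MISSING, 1], [1, 0, 1, 0]])
        merged = merge_duplicates(calls, [["s0"]], seed=1)
        np.testing.assert_array_equal(merged.row("s0"), calls.row("s0"))

    def test_missing_filled_from_partner(self):
        calls = call_matrix([[MISSING, 1], [1, MISSING]], names=["a", "b"])
        merged = merge_duplicates(calls, [["a", "b"]], seed=1)
        np.testing.assert_array_equal(merged.row("a"), [1, 1])

    def test_overlapping_groups_rejected(self):
        calls = call_matrix([[0], [1], [0]])
        with pytest.raises(ValueError):
            merge_duplicates(calls, [["s0", "s1"], ["s1", "s2"]])

    @given(st.integers(0, 2**31 - 1))
    def test_merged_missingness_never_exceeds_members(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.choice([0, 1, MISSING], size=(3, 200),
                          p=[0.4, 0.3, 0.3]).astype(np.int8)
        calls = call_matrix(vals)
        merged = merge_duplicates(calls, [["s0", "s1", "s2"]], seed=seed)
        member_missing = (vals == MISSING).mean(axis=1).min()
        merged_missing = (merged.values[0] == MISSING).mean()
        assert merged_missing <= member_missing
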