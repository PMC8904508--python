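"""f-statistics estimators against brute-force and closed-form oracles."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from adnakit import (
    AdmixtureGraph,
    AlleleCounts,
    BlockPartition,
    SNPPanel,
    block_jackknife,
    f2,
    f3,
    f4,
    simulate_frequencies,
)
from adnakit.fstats import f2_per_snp, f3_per_snp, f4_per_snp

from conftest import E_P1MP, counts_from_freqs, exact_f2_expectation


@pytest.fixture(scope="module")
def trio_counts(outgroup_trio):
    _, panel, freqs = outgroup_trio
    return (
        counts_from_freqs(freqs),
        BlockPartition.from_panel(panel),
        panel,
    )


class TestPerSnp:
    def test_f2_identical_zero(self):
        counts = AlleleCounts(["A", "B"], [[3, 5], [3, 5]], [[10, 10], [10, 10]])
        v, valid = f2_per_snp(counts, "A", "B", corrected=False)
        assert np.all(v[valid] == 0)

    def test_f2_fixed_difference(self):
        counts = AlleleCounts(["A", "B"], [[1000], [0]], [[1000], [1000]])
        v, _ = f2_per_snp(counts, "A", "B", corrected=True)
        assert v[0] == pytest.approx(1.0, abs=1e-3)

    def test_f3_on_identical_pops_uncorrected_zero(self):
        counts = AlleleCounts(["C", "A", "B"], [[4, 2]] * 3, [[10, 10]] * 3)
        v, valid = f3_per_snp(counts, "C", "A", "B", corrected=False)
        assert np.all(v[valid] == 0)

    def test_f4_same_right_args_zero(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 10, size=(3, 50))
        counts = AlleleCounts(
            ["A", "B", "C"], x, np.full((3, 50), 10.0)
        )
        v, _ = f4_per_snp(counts, "A", "B", "C", "C")
        assert np.all(v == 0)

    def test_f4_antisymmetry(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 10, size=(4, 50))
        counts = AlleleCounts(list("ABCD"), x, np.full((4, 50), 10.0))
        v1, _ = f4_per_snp(counts, "A", "B", "C", "D")
        v2, _ = f4_per_snp(counts, "B", "A", "C", "D")
        np.testing.assert_allclose(v1, -v2, atol=1e-15)


class TestJackknife:
    def test_identical_blocks_zero_se(self):
        values = np.tile([1.0, 2.0, 3.0], 10)
        part = BlockPartition(np.repeat(np.arange(10), 3))
        est, se, _, _ = block_jackknife(values, part)
        assert est == pytest.approx(2.0)
        assert se == pytest.approx(0.0, abs=1e-12)

    def test_equal_weights_matches_delete1_bruteforce(self):
        rng = np.random.default_rng(2)
        values = rng.normal(size=120)
        part = BlockPartition(np.repeat(np.arange(12), 10))
        est, se, _, _ = block_jackknife(values, part)
        assert est == pytest.approx(values.mean(), abs=1e-12)
        # brute-force delete-1 jackknife over blocks
        loo = np.array(
            [np.delete(values.reshape(12, 10), j, axis=0).mean()
             for j in range(12)]
        )
        g = 12
        se_brute = np.sqrt((g - 1) / g * ((loo - loo.mean()) ** 2).sum())
        assert se == pytest.approx(se_brute, abs=1e-12)

    def test_single_block_errors(self):
        with pytest.raises(ValueError):
            block_jackknife(np.ones(10), BlockPartition(np.zeros(10)))

    @given(st.integers(0, 10_000))
    def test_block_relabeling_invariance(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.normal(size=60)
        ids = rng.integers(0, 6, size=60)
        relabel = rng.permutation(6) * 13 + 7  # injective id remap
        est1, se1, _, _ = block_jackknife(values, BlockPartition(ids))
        est2, se2, _, _ = block_jackknife(
            values, BlockPartition(relabel[ids])
        )
        assert est1 == pytest.approx(est2, abs=1e-12)
        assert se1 == pytest.approx(se2, abs=1e-12)


class TestAggregates:
    def test_blocked_aggregate_equals_naive_mean(self, trio_counts):
        counts, part, _ = trio_counts
        r = f4(counts, "O", "A", "O", "B", part)
        o, a, b = (counts.freq(p) for p in ("O", "A", "B"))
        naive = np.mean((o - a) * (o - b))
        assert r.estimate == pytest.approx(naive, abs=1e-12)

    def test_f3_matches_shared_drift(self, trio_counts):
        counts, part, _ = trio_counts
        r = f3(counts, "O", "A", "B", part, corrected=False)
        assert abs(r.estimate - 0.02 * E_P1MP) < 3 * r.se

    def test_f4_identity_with_f2(self, trio_counts):
        counts, part, _ = trio_counts
        r4 = f4(counts, "A", "B", "A", "B", part)
        r2 = f2(counts, "A", "B", part, corrected=False)
        assert r4.estimate == pytest.approx(r2.estimate, abs=1e-14)

    def test_snp_order_invariance(self, trio_counts):
        counts, part, panel = trio_counts
        rng = np.random.default_rng(3)
        perm = rng.permutation(counts.n_snps)
        shuffled = AlleleCounts(
            counts.pops, counts.x[:, perm], counts.n[:, perm]
        )
        part2 = BlockPartition(part.block_ids[perm])
        r1 = f4(counts, "O", "A", "O", "B", part)
        r2 = f4(shuffled, "O", "A", "O", "B", part2)
        assert r1.estimate == pytest.approx(r2.estimate, abs=1e-14)
        assert r1.se == pytest.approx(r2.se, abs=1e-14)

    def test_no_overlap_errors(self):
        counts = AlleleCounts(["A", "B"], [[0], [0]], [[0], [1]])
        part = BlockPartition(np.zeros(1))
        with pytest.raises(ValueError):
            f2(counts, "A", "B", part)


class TestCorrectedVsTruth:
    def test_correction_removes_sampling_bias(self):
        # uncorrected on true freqs == expectation of corrected on counts
        graph = AdmixtureGraph(
            [("root", "A", 0.01), ("root", "B", 0.02)]
        )
        panel = SNPPanel.uniform(50_000, n_chrom=10)
        freqs = simulate_frequencies(graph, panel, seed=55)
        part = BlockPartition.from_panel(panel)
        truth = f2(
            counts_from_freqs(freqs), "A", "B", part, corrected=False
        ).estimate
        sampled = counts_from_freqs(freqs, rng_seed=7, n_alleles=10)
        corrected = f2(sampled, "A", "B", part, corrected=True)
        assert abs(corrected.estimate - truth) < 3 * corrected.se

    def test_jackknife_se_close_to_replicate_sd(self):
        # compact version of the calibration experiment (full one in the
        # acceptance suite): SE from one replicate vs SD across replicates
        graph = AdmixtureGraph([("root", "A", 0.01), ("root", "B", 0.01)])
        panel = SNPPanel.uniform(500, n_chrom=10)
        part = BlockPartition.from_panel(panel)
        ests, ses = [], []
        for rep in range(60):
            freqs = simulate_frequencies(graph, panel, seed=900 + rep)
            r = f2(counts_from_freqs(freqs), "A", "B", part, corrected=False)
            ests.append(r.estimate)
            ses.append(r.se)
        ratio = np.median(ses) / np.std(ests, ddof=1)
        assert 0.7 < ratio < 1.3


class TestBatch:
    def test_poplist_file_batches_statistics(self, trio_counts, tmp_path):
        from adnakit.fstats import batch_fstats

        counts, part, _ = trio_counts
        listing = tmp_path / "qp3pop.txt"
        listing.write_text("# outgroup-f3 batch\nO A B\n\nO B A\n")
        results = batch_fstats("f3", counts, str(listing), part,
                               corrected=False)
        assert len(results) == 2
        assert results[0].pops == ("O", "A", "B")
        assert results[0].estimate == pytest.approx(results[1].estimate)

    def test_poplist_arity_checked(self, trio_counts):
        from adnakit.fstats import batch_fstats

        counts, part, _ = trio_counts
        with pytest.raises(ValueError, match="line 1"):
            batch_fstats("f4", counts, ["O A B"], part)
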