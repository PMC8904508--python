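"""Sliding-window selection scan: windowing, normalization, z-scores."""

import numpy as np
import pandas as pd
import pytest

from adnakit import AlleleCounts, BlockPartition, simulate_frequencies
from adnakit.designs import sample_counts, scan_design
from adnakit.scan import (
    WindowSpec,
    allele_frequency,
    blocks_from_tiling,
    call_candidates,
    ldblock_zscores,
    read_bed,
    window_scan,
)

N_T, N_A, N_O = 54, 17, 100  # alleles: 27 diploid, 17 haploid, 50 diploid


def scan_counts(seed, spike_window=None, spike_shift=0.35):
    """Null (or spiked) scan fixture: counts plus panel and coverage."""
    graph, panel = scan_design()
    freqs = simulate_frequencies(graph, panel, seed=seed)
    if spike_window is not None:
        chrom, start, end = spike_window
        m = (panel.chrom == chrom) & (panel.pos >= start) & (panel.pos < end)
        # selection proxy: push target frequencies away post-split
        shifted = freqs.freqs.copy()
        i = freqs.pops.index("target")
        shifted[i, m] = np.clip(shifted[i, m] + spike_shift, 0, 1)
        freqs = type(freqs)(freqs.pops, shifted, freqs.root_beta)
    counts = sample_counts(
        freqs, {"target": N_T, "ancient": N_A, "outgroup": N_O}, seed=seed,
        haploid_pops=frozenset(["ancient"]),
    )
    coverage = np.full(len(panel), 17)
    return counts, coverage, panel


@pytest.fixture(scope="module")
def null_scan():
    counts, coverage, panel = scan_counts(seed=301)
    stats = window_scan(counts, coverage, panel, WindowSpec())
    blocks = blocks_from_tiling(panel, 2_000_000)
    return ldblock_zscores(stats, blocks, seed=301), panel


class TestWindowing:
    def test_low_snp_windows_carry_no_statistics(self):
        counts, coverage, panel = scan_counts(seed=303)
        spec = WindowSpec(min_snps=100_000)  # nothing qualifies
        with pytest.raises(ValueError):
            window_scan(counts, coverage, panel, spec)
        spec2 = WindowSpec(min_snps=250)
        stats = window_scan(counts, coverage, panel, spec2)
        low = stats[stats["n_snps"] < 250]
        assert low["raw_f3"].isna().all()
        high = stats[stats["n_snps"] >= 250]
        assert np.isfinite(high["raw_f3"]).all()

    def test_ancient_coverage_threshold_strict(self):
        counts, coverage, panel = scan_counts(seed=305)
        spec = WindowSpec()
        coverage15 = np.full(len(panel), 15)  # not strictly greater than 15
        with pytest.raises(ValueError):  # every SNP excluded, no window left
            window_scan(counts, coverage15, panel, spec)
        stats = window_scan(counts, np.full(len(panel), 16), panel, spec)
        assert np.isfinite(stats["raw_f3"]).any()

    def test_window_tiling_anchored_at_step_multiples(self, null_scan):
        stats, _ = null_scan
        assert (stats["start"] % 10_000 == 0).all()
        assert ((stats["end"] - stats["start"]) == 500_000).all()

    def test_normalized_statistic_scale_free(self, null_scan):
        stats, _ = null_scan
        ok = np.isfinite(stats["norm_f3"])
        np.testing.assert_allclose(
            stats.loc[ok, "norm_f3"],
            (3.0 * stats.loc[ok, "raw_f3"]) / (3.0 * stats.loc[ok, "het"]),
        )


class TestZScores:
    def test_null_z_centered_unit_scale(self, null_scan):
        stats, _ = null_scan
        z = stats["z"][np.isfinite(stats["z"])]
        assert abs(z.mean()) < 0.1
        assert 0.8 < z.std() < 1.2

    def test_degenerate_constant_values(self, null_scan):
        stats, panel = null_scan
        flat = stats.copy()
        flat["norm_f3"] = np.where(
            np.isfinite(flat["norm_f3"]), 1.0, np.nan
        )
        blocks = blocks_from_tiling(panel, 2_000_000)
        out = ldblock_zscores(flat, blocks, seed=1)
        assert out.attrs["degenerate"]
        assert out["z"].isna().all()

    def test_too_few_blocks_rejected(self, null_scan):
        stats, panel = null_scan
        blocks = blocks_from_tiling(panel, 200_000_000)  # one block/chrom
        with pytest.raises(ValueError):
            ldblock_zscores(stats.head(50), blocks.head(2), seed=1)

    def test_spiked_window_top_ranked_above_four(self):
        spike = ("3", 4_000_000, 4_500_000)
        counts, coverage, panel = scan_counts(seed=307, spike_window=spike)
        stats = window_scan(counts, coverage, panel, WindowSpec())
        blocks = blocks_from_tiling(panel, 2_000_000)
        stats = ldblock_zscores(stats, blocks, seed=307)
        top = stats.loc[stats["z"].idxmax()]
        assert top["chrom"] == "3"
        assert spike[1] - 500_000 <= top["start"] <= spike[2]
        assert top["z"] > 4


class TestCandidates:
    def test_empty_below_threshold(self, null_scan):
        stats, _ = null_scan
        out = call_candidates(stats, z_threshold=np.inf)
        assert len(out) == 0

    def test_overlapping_windows_merge_and_annotate(self):
        spike = ("3", 4_000_000, 4_500_000)
        counts, coverage, panel = scan_counts(seed=309, spike_window=spike)
        stats = window_scan(counts, coverage, panel, WindowSpec())
        blocks = blocks_from_tiling(panel, 2_000_000)
        stats = ldblock_zscores(stats, blocks, seed=309)
        genes = pd.DataFrame(
            {"chrom": ["3"], "start": [4_100_000], "end": [4_200_000],
             "name": ["EPAS1-like"]}
        )
        regions = call_candidates(stats, z_threshold=4, genes=genes)
        assert len(regions) == 1  # overlapping hits merged
        assert "EPAS1-like" in regions["genes"].iloc[0]

    def test_bed_read_converts_coordinates(self, tmp_path):
        bed = tmp_path / "b.bed"
        bed.write_text("1\t0\t1000\tfirst\n2\t500\t900\tsecond\n")
        df = read_bed(bed)
        assert df["start"].tolist() == [1, 501]
        assert df["end"].tolist() == [1001, 901]


class TestAlleleFrequency:
    def test_point_estimate(self):
        freq, (lo, hi), n = allele_frequency(9, 12)
        assert freq == pytest.approx(0.75)
        assert lo < 0.75 < hi

    def test_zero_of_n(self):
        freq, (lo, hi), _ = allele_frequency(0, 25)
        assert freq == 0.0
        assert lo == pytest.approx(0.0, abs=1e-12)

    def test_zero_called_rejected(self):
        with pytest.raises(ValueError):
            allele_frequency(0, 0)

    def test_wilson_interval_coverage(self):
        rng = np.random.default_rng(99)
        p, n = 0.4, 40
        covered = 0
        reps = 1000
        for _ in range(reps):
            x = rng.binomial(n, p)
            _, (lo, hi), _ = allele_frequency(int(x), n)
            covered += lo <= p <= hi
        assert 0.93 <= covered / reps <= 0.98
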