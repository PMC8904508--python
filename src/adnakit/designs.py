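"""Canonical synthetic study designs used by the recovery experiments.

Each function returns the pieces of one simulation design — an admixture
graph, a marker panel, cohort sizes — at the scale the package's validation
experiments run at. Drift lengths are in f2 units on a Beta(0.46, 0.46)
root (heterozygosity ~0.24); panels use the uniform 1 cM/Mb map. The
designs are fixed: recovery tests, the bundled examples, and the
acceptance experiments all draw from here, varying only seeds.
"""

from __future__ import annotations

import numpy as np

from .fstats import AlleleCounts, BlockPartition
from .graph import AdmixtureGraph
from .panel import SNPPanel
from .qpadm import LeftRightConfig
from .simulate import FreqTable, simulate_frequencies

__all__ = [
    "pmr_panel",
    "qpadm_design",
    "cladal_design",
    "five_leaf_design",
    "dating_design",
    "scan_design",
    "sample_counts",
]


def pmr_panel(n_snps: int = 50_000) -> SNPPanel:
    """Single-population panel for mismatch-rate experiments."""
    return SNPPanel.uniform(n_snps)


def qpadm_design(n_snps: int = 100_000, alpha: float = 0.7):
    """Two-way admixed target with six outgroups of graded divergence.

    The rights O5/O6 split inside the source clade, so they differentiate
    the two sources; the target T draws ``alpha`` of its ancestry from the
    S1 side. O7 is a deeply diverged population used as a wrong-source
    stand-in for infeasible-model experiments.
    """
    edges = [
        ("root", "O1", 0.10), ("root", "x0", 0.01),
        ("x0", "O7", 0.08), ("x0", "x1", 0.01),
        ("x1", "O2", 0.08), ("x1", "x2", 0.02),
        ("x2", "O3", 0.08), ("x2", "x3", 0.02),
        ("x3", "O4", 0.06), ("x3", "y", 0.02),
        ("y", "O5", 0.05), ("y", "z", 0.02),
        ("z", "S1a", 0.01), ("z", "w", 0.02),
        ("w", "O6", 0.05), ("w", "S2a", 0.02),
        ("S1a", "S1", 0.01), ("S2a", "S2", 0.01),
        ("T0", "T", 0.005),
    ]
    graph = AdmixtureGraph(edges, {"T0": ("S1a", "S2a", alpha)})
    panel = SNPPanel.uniform(n_snps // 20, n_chrom=20)
    config = LeftRightConfig(
        ["T", "S1", "S2"], ["O1", "O2", "O3", "O4", "O5", "O6"]
    )
    return graph, panel, config


def cladal_design(n_snps: int = 20_000, cladal: bool = True):
    """Left pair against six rights; cladal (A/B split after every right
    diverged) or not (B carries extra shared drift with the O5/O6 side)."""
    edges = [
        ("root", "O1", 0.10), ("root", "x1", 0.02),
        ("x1", "O2", 0.08), ("x1", "x2", 0.02),
        ("x2", "O3", 0.08), ("x2", "x3", 0.02),
        ("x3", "O4", 0.06), ("x3", "y", 0.02),
        ("y", "O5", 0.05), ("y", "z", 0.02),
        ("z", "O6", 0.05), ("z", "ab", 0.02),
    ]
    if cladal:
        edges += [("ab", "A", 0.01), ("ab", "B", 0.01)]
        graph = AdmixtureGraph(edges)
    else:
        edges += [("ab", "A", 0.01), ("y", "B", 0.02)]
        graph = AdmixtureGraph(edges)
    panel = SNPPanel.uniform(n_snps // 20, n_chrom=20)
    config = LeftRightConfig(
        ["A", "B"], ["O1", "O2", "O3", "O4", "O5", "O6"]
    )
    return graph, panel, config


def five_leaf_design(n_snps: int = 80_000, alpha: float = 0.4):
    """Five-leaf skeleton with one admixed leaf (E), plus the same graph
    with F attached mid-edge for leaf-addition recovery."""
    edges = [
        ("root", "O", 0.08), ("root", "x1", 0.02),
        ("x1", "A", 0.03), ("x1", "x2", 0.015),
        ("x2", "B", 0.02), ("x2", "x3", 0.01),
        ("x3", "C", 0.02), ("x3", "D0", 0.004),
        ("D0", "D", 0.01), ("E0", "E", 0.012),
    ]
    graph = AdmixtureGraph(edges, {"E0": ("x2", "x3", alpha)})
    panel = SNPPanel.uniform(n_snps // 20, n_chrom=20)
    return graph, panel


def leaf_addition_design(n_snps: int = 80_000):
    """Truth: F sits mid-way on the x1->x2 edge of a five-leaf tree."""
    truth = AdmixtureGraph(
        [
            ("root", "O", 0.08), ("root", "x1", 0.02),
            ("x1", "A", 0.03), ("x1", "m", 0.008),
            ("m", "F", 0.02), ("m", "x2", 0.007),
            ("x2", "B", 0.02), ("x2", "x3", 0.01),
            ("x3", "C", 0.02), ("x3", "D", 0.015),
        ]
    )
    base = AdmixtureGraph(
        [
            ("root", "O", 0.08), ("root", "x1", 0.02),
            ("x1", "A", 0.03), ("x1", "x2", 0.015),
            ("x2", "B", 0.02), ("x2", "x3", 0.01),
            ("x3", "C", 0.02), ("x3", "D", 0.015),
        ]
    )
    panel = SNPPanel.uniform(n_snps // 20, n_chrom=20)
    return truth, base, panel, "edge:x1->x2"


def dating_design(n_snps_per_chrom: int = 800, n_chrom: int = 20):
    """Two sources at moderate divergence, 20 chromosomes of 1 Morgan."""
    graph = AdmixtureGraph([("root", "S1", 0.05), ("root", "S2", 0.05)])
    panel = SNPPanel.uniform(n_snps_per_chrom, n_chrom=n_chrom)
    return graph, panel


def scan_design(n_snps_per_chrom: int = 6_000, n_chrom: int = 10):
    """Target/ancient sister pair with an outgroup; ~1.7 kb SNP spacing on
    10 Mb chromosomes so a 500 kb window holds ~300 SNPs."""
    graph = AdmixtureGraph(
        [
            ("root", "anc", 0.01), ("anc", "target", 0.01),
            ("anc", "ancient", 0.005), ("root", "outgroup", 0.02),
        ]
    )
    panel = SNPPanel.uniform(
        n_snps_per_chrom, n_chrom=n_chrom, chrom_length_bp=10_000_000
    )
    return graph, panel


def sample_counts(
    freqs: FreqTable,
    n_alleles: int | dict[str, int],
    seed: int,
    haploid_pops: frozenset = frozenset(),
) -> AlleleCounts:
    """Binomial allele-count sampling from population frequencies."""
    rng = np.random.default_rng(seed)
    x = np.empty_like(freqs.freqs)
    n = np.empty_like(freqs.freqs)
    for i, pop in enumerate(freqs.pops):
        ni = n_alleles[pop] if isinstance(n_alleles, dict) else n_alleles
        x[i] = rng.binomial(ni, freqs.freqs[i])
        n[i] = ni
    return AlleleCounts(list(freqs.pops), x, n, haploid_pops)
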