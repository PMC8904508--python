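"""Duplicate and relative detection from pseudo-haploid mismatch rates.

Simulates a 12-person cohort with a duplicate pair, a parent-offspring
pair, and a half-sibling pair, draws one random allele per site per
person, and classifies all pairs by their pairwise mismatch rate (PMR).
Expected scales: duplicates ~0.12, first degree ~0.18, unrelated ~0.24.
"""

from adnakit import AdmixtureGraph, SNPPanel, simulate_frequencies, simulate_genotypes
from adnakit.relatedness import estimate_baseline, pairwise_mismatch, pmr_report
from adnakit.simulate import CohortSpec, random_allele_calls

panel = SNPPanel.uniform(50_000)
graph = AdmixtureGraph([("root", "P", 0.0)])
freqs = simulate_frequencies(graph, panel, seed=7)
cohort = CohortSpec(
    groups={"P": 12},
    pedigree=[
        ("P0", "P1", "duplicate"),
        ("P2", "P3", "parent_offspring"),
        ("P4", "P5", "second_degree"),
    ],
)
genotypes = simulate_genotypes(freqs, cohort, seed=7, panel=panel)
calls = random_allele_calls(genotypes, seed=7)

results, _ = pairwise_mismatch(calls)
baseline = estimate_baseline(results)
report = pmr_report(results, baseline)

print(f"cohort baseline (unrelated PMR) B = {baseline:.4f}")
print(report[report["class"] != "unrelated"].to_string(index=False))
# Each flagged pair's pmr sits near (1 - kinship) * B: the duplicate near
# B/2, the parent-offspring pair near 0.75 B, the half sibs near 0.875 B.
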