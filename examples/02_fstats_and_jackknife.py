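"""Outgroup-f3 and f4 statistics with 5 cM block-jackknife errors.

Simulates five populations where A and B share 0.02 of post-outgroup
drift. f3(O; A, B) measures the drift shared by A and B as seen from O —
here the O branch (0.05) plus the common x branch (0.02), times
E[p(1-p)] ~ 0.12, so ~0.0084. f4(O, A; B, C) tests whether B and C are
symmetric with respect to A: B shares the x branch with A while C does
not, so the expectation is -0.02 * 0.12 ~ -0.0024 with a strongly
negative z.
"""

from adnakit import AdmixtureGraph, BlockPartition, SNPPanel, simulate_frequencies
from adnakit.designs import sample_counts
from adnakit.fstats import f3, f4

graph = AdmixtureGraph(
    [("root", "O", 0.05), ("root", "x", 0.02),
     ("x", "A", 0.01), ("x", "B", 0.015), ("root", "C", 0.03)]
)
panel = SNPPanel.uniform(5_000, n_chrom=20)
freqs = simulate_frequencies(graph, panel, seed=11)
counts = sample_counts(freqs, 40, seed=11)  # 20 diploids per population
blocks = BlockPartition.from_panel(panel, span_cM=5.0)

r3 = f3(counts, "O", "A", "B", blocks)
print(f"f3(O; A, B) = {r3.estimate:.5f} +- {r3.se:.5f}  (z = {r3.z:.1f})")
print("  expectation: (0.05 + 0.02) shared drift * E[p(1-p)] ~ 0.0084")

r4 = f4(counts, "O", "A", "B", "C", blocks)
print(f"f4(O, A; B, C) = {r4.estimate:.6f} +- {r4.se:.6f}  (z = {r4.z:.1f})")
print("  expectation ~ -0.0024: B shares drift with A, C does not")
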