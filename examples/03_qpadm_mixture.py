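"""qpAdm: estimate admixture proportions against a set of outgroups.

The target T was simulated as a 70/30 mixture of the two sources. qpAdm
solves for weights summing to 1 that make the target's f4 sharing with
six outgroups a combination of the sources', and the tail p-value tests
whether two sources suffice.
"""

from adnakit import BlockPartition, simulate_frequencies
from adnakit.designs import qpadm_design, sample_counts
from adnakit.qpadm import qpadm_weights

graph, panel, config = qpadm_design(n_snps=100_000, alpha=0.7)
freqs = simulate_frequencies(graph, panel, seed=3)
counts = sample_counts(freqs, 40, seed=3)
blocks = BlockPartition.from_panel(panel)

res = qpadm_weights(counts, config, blocks, seed=3)
for src, w, se in zip(res.sources, res.weights, res.se):
    print(f"  {src}: {w:.3f} +- {se:.3f}")
print(f"tail p = {res.p_value:.3f}  feasible = {res.feasible}")
# Weights should bracket the simulated 0.70/0.30 split within ~2 SE; a
# small tail p or weights outside [0, 1] would reject the model.
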