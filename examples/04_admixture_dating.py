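"""Date an admixture pulse from ancestry-covariance decay.

Simulates 20 diploid individuals whose ancestors mixed 46 generations ago
and fits A exp(-g d) + c to the weighted covariance of ancestry-informative
alleles as a function of genetic distance d. The decay rate g is the
admixture age in generations.
"""

from adnakit import AdmixedSampleSpec, simulate_admixed_genotypes, simulate_frequencies
from adnakit.dating import ancestry_covariance, fit_decay
from adnakit.designs import dating_design

graph, panel = dating_design()
freqs = simulate_frequencies(graph, panel, seed=46)
spec = AdmixedSampleSpec("S1", "S2", alpha=0.5, generations=46,
                         n_individuals=20)
genotypes, _, _ = simulate_admixed_genotypes(spec, freqs, panel, seed=46)

curve = ancestry_covariance(
    genotypes, freqs.freq("S1"), freqs.freq("S2"), panel,
    binsize_cM=0.25, max_dist_cM=100.0,
)
fit = fit_decay(curve)
print(f"estimated admixture age: {fit.generations:.1f} +- {fit.se:.1f} "
      f"generations (truth: 46)")
print(f"amplitude {fit.amplitude:.2e}, offset {fit.offset:.2e}, "
      f"fit window {fit.fit_window_cM[0]:.2f}-{fit.fit_window_cM[1]:.2f} cM")
# With a known generation time the age converts to years:
print(f"at 29 years/generation: {fit.years(29):.0f} years before sampling")
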