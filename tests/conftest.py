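import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

from adnakit import (
    AdmixtureGraph,
    AlleleCounts,
    BlockPartition,
    SNPPanel,
    simulate_frequencies,
)

# expected het/2 for the default Beta(0.46, 0.46) root: a*b/((a+b)(a+b+1))
E_P1MP = 0.46 * 0.46 / (0.92 * 1.92)


def exact_f2_expectation(graph: AdmixtureGraph, a: str, b: str,
                         root_p1mp: float = E_P1MP) -> float:
    """Closed-form E[(p_a - p_b)^2] for two leaves of a drift tree.

    Uses the exact Balding-Nichols second-moment recursion: along an edge
    with drift c, E[p(1-p)] shrinks by (1-c) and E[(child-parent)^2] =
    c * E[p_parent(1-p_parent)]. Valid for admixture-free leaf pairs whose
    paths to the MRCA are disjoint.
    """
    def path_to_root(node):
        path = []
        while node != graph.root:
            parent, c = graph.drift_parent(node)
            path.append((parent, node, c))
            node = parent
        return path[::-1]

    pa, pb = path_to_root(a), path_to_root(b)
    shared = 0
    while shared < min(len(pa), len(pb)) and pa[shared] == pb[shared]:
        shared += 1
    h = root_p1mp
    for _, _, c in pa[:shared]:
        h *= 1 - c
    out = 0.0
    for branch in (pa[shared:], pb[shared:]):
        hh = h
        for _, _, c in branch:
            out += c * hh
            hh *= 1 - c
    return out


@pytest.fixture(scope="session")
def outgroup_trio():
    """Outgroup at the root, A/B sharing 0.02 drift: the closed-form
    shared-drift fixture (E f3(O;A,B) = 0.02 * E[p(1-p)] ~ 0.0024)."""
    graph = AdmixtureGraph(
        [("root", "O", 0.0), ("root", "X", 0.02),
         ("X", "A", 0.0), ("X", "B", 0.0)]
    )
    panel = SNPPanel.uniform(100_000, n_chrom=20)
    freqs = simulate_frequencies(graph, panel, seed=4242)
    return graph, panel, freqs


@pytest.fixture(scope="session")
def small_panel():
    return SNPPanel.uniform(2_000, n_chrom=4)


def counts_from_freqs(freqs, rng_seed=0, n_alleles=None):
    """Exact frequencies (n_alleles=None) or binomially sampled counts."""
    if n_alleles is None:
        return AlleleCounts.from_frequencies(freqs.pops, freqs.freqs)
    rng = np.random.default_rng(rng_seed)
    x = rng.binomial(n_alleles, freqs.freqs).astype(float)
    n = np.full_like(x, float(n_alleles))
    return AlleleCounts(freqs.pops, x, n)
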