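"""Synthetic-data generator with known ground truth.

Every input the pipeline consumes can be generated here: population allele
frequencies drifting along an admixture graph (Balding-Nichols draws),
diploid genotypes including pedigree relatives, sequencing-read pileups with
terminal deamination damage, and admixed chromosomes with exponentially
distributed ancestry tracts. The same containers feed recovery tests, so
each generator records the ground truth it used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import stream
from .graph import AdmixtureGraph
from .matrix import MISSING, GenotypeMatrix
from .panel import SNPPanel

__all__ = [
    "FreqTable",
    "CohortSpec",
    "AdmixedSampleSpec",
    "simulate_frequencies",
    "simulate_genotypes",
    "simulate_pileup",
    "simulate_admixed_genotypes",
    "random_allele_calls",
    "DEFAULT_ROOT_BETA",
]

# Root frequency spectrum Beta(0.46, 0.46): expected heterozygosity
# 2*E[p(1-p)] ~= 0.2396, putting unrelated-pair mismatch rates of
# pseudo-haploid calls on the ~0.24 scale typical of 1240K-style panels.
DEFAULT_ROOT_BETA = (0.46, 0.46)

RELATIONS = ("duplicate", "parent_offspring", "full_sib", "second_degree")


@dataclass
class FreqTable:
    """Population-by-SNP allele frequency matrix."""

    pops: list[str]
    freqs: np.ndarray  # (n_pops, n_snps) in [0, 1]
    root_beta: tuple[float, float] = DEFAULT_ROOT_BETA
    n_clipped: int = 0

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=np.float64)
        if self.freqs.shape[0] != len(self.pops):
            raise ValueError("freqs rows do not match pops")
        if np.any((self.freqs < 0) | (self.freqs > 1)):
            raise ValueError("frequencies outside [0, 1]")

    def freq(self, pop: str) -> np.ndarray:
        return self.freqs[self.pops.index(pop)]


@dataclass
class CohortSpec:
    """Sampling design for one or more population cohorts.

    ``groups`` maps a population label (a row of the frequency table) to a
    number of diploid individuals, named ``{group}{i}``. ``pedigree`` lists
    (indA, indB, relation) links imposed on otherwise-unrelated draws, with
    relation one of ``duplicate | parent_offspring | full_sib |
    second_degree`` (realized as half siblings, kinship 1/8).
    """

    groups: dict[str, int]
    pedigree: list[tuple[str, str, str]] = field(default_factory=list)
    mean_depth: float | dict[str, float] = 1.0
    library_type: str | dict[str, str] = "double_strand"
    damage_rate: float | dict[str, float] = 0.0

    def __post_init__(self):
        group_of = {n: g for n, g in self.individuals()}
        for a, b, rel in self.pedigree:
            if rel not in RELATIONS:
                raise ValueError(f"unknown relation {rel!r}")
            if a not in group_of or b not in group_of:
                raise ValueError(f"pedigree link references unknown {a!r}/{b!r}")
            if group_of[a] != group_of[b]:
                raise ValueError("pedigree links must stay within one group")
        for lam in self._per_individual(self.mean_depth).values():
            if not np.isfinite(lam) or lam < 0:
                raise ValueError("mean depth must be finite and >= 0")
        for d in self._per_individual(self.damage_rate).values():
            if not 0.0 <= d <= 1.0:
                raise ValueError("damage rate must lie in [0, 1]")

    def individuals(self) -> list[tuple[str, str]]:
        """(name, group) pairs in deterministic order."""
        return [
            (f"{g}{i}", g) for g in self.groups for i in range(self.groups[g])
        ]

    def _per_individual(self, value) -> dict:
        if isinstance(value, dict):
            return dict(value)
        return {name: value for name, _ in self.individuals()}

    def depth_of(self, ind: str) -> float:
        return self._per_individual(self.mean_depth).get(ind, 0.0)

    def library_type_of(self, ind: str) -> str:
        lt = self._per_individual(self.library_type).get(ind, "double_strand")
        if lt not in ("double_strand", "single_strand"):
            raise ValueError(f"unknown library type {lt!r}")
        return lt

    def damage_of(self, ind: str) -> float:
        return self._per_individual(self.damage_rate).get(ind, 0.0)


@dataclass
class AdmixedSampleSpec:
    """A two-way admixture pulse sampled after ``generations`` of recombination."""

    source1: str
    source2: str
    alpha: float  # fraction of ancestry from source1
    generations: float
    n_individuals: int

    def __post_init__(self):
        if self.generations <= 0:
            raise ValueError("generations must be > 0")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")


# ---------------------------------------------------------------------------
# allele frequencies along a graph
# ---------------------------------------------------------------------------


def _balding_nichols(p: np.ndarray, c: float, rng) -> tuple[np.ndarray, int]:
    """Child frequencies with mean p and variance c*p*(1-p).

    Beta draw with matched moments; for c >= 1 the requested variance exceeds
    what a Beta supports and the draw truncates to {0, 1} (a Bernoulli(p)).
    Returns (frequencies, number of fixation/truncation events).
    """
    if c == 0:
        return p.copy(), 0
    out = p.copy()
    live = (p > 0) & (p < 1)  # fixed sites stay fixed: variance is 0
    if c >= 1.0:
        out[live] = (rng.random(live.sum()) < p[live]).astype(float)
        return out, int(np.isin(out[live], (0.0, 1.0)).sum())
    k = (1.0 - c) / c
    out[live] = rng.beta(p[live] * k, (1.0 - p[live]) * k)
    return out, int(((out[live] == 0.0) | (out[live] == 1.0)).sum())


def simulate_frequencies(
    graph: AdmixtureGraph,
    panel: SNPPanel,
    seed: int,
    root_beta: tuple[float, float] = DEFAULT_ROOT_BETA,
    keep_internal: bool = False,
) -> FreqTable:
    """Drift allele frequencies from a Beta root down an admixture graph.

    The root draws i.i.d. Beta(a, b) frequencies (monomorphic draws are
    redrawn); each drift edge applies a Balding-Nichols perturbation; each
    admixture node mixes its parents linearly by alpha. Only leaf rows are
    returned unless ``keep_internal``.
    """
    if len(panel) == 0:
        raise ValueError("panel is empty")
    a, b = root_beta
    n = len(panel)
    rng_root = stream(seed, "freqs", graph.root)
    p_root = rng_root.beta(a, b, size=n)
    for _ in range(100):
        mono = (p_root == 0.0) | (p_root == 1.0)
        if not mono.any():
            break
        p_root[mono] = rng_root.beta(a, b, size=int(mono.sum()))

    freqs: dict[str, np.ndarray] = {graph.root: p_root}
    n_clipped = 0
    for node in graph.topological_order():
        if node == graph.root:
            continue
        if node in graph.admixtures:
            pa, pb, alpha = graph.admixtures[node]
            freqs[node] = alpha * freqs[pa] + (1 - alpha) * freqs[pb]
        else:
            parent, c = graph.drift_parent(node)
            rng = stream(seed, "freqs", node)
            freqs[node], clipped = _balding_nichols(freqs[parent], c, rng)
            n_clipped += clipped

    pops = graph.nodes if keep_internal else graph.leaves
    mat = np.vstack([freqs[p] for p in pops])
    return FreqTable(list(pops), mat, root_beta=root_beta, n_clipped=n_clipped)


# ---------------------------------------------------------------------------
# genotypes, pedigrees
# ---------------------------------------------------------------------------


def _transmit(parent_geno: np.ndarray, rng) -> np.ndarray:
    """One allele per site drawn from a diploid parent (Mendelian)."""
    allele = np.where(parent_geno == 1, rng.integers(0, 2, parent_geno.shape),
                      parent_geno // 2)
    return allele.astype(np.int8)


def simulate_genotypes(
    freqs: FreqTable,
    cohort: CohortSpec,
    seed: int,
    panel: SNPPanel | None = None,
) -> GenotypeMatrix:
    """Diploid Hardy-Weinberg genotypes with optional pedigree links.

    Unrelated individuals draw Binomial(2, p) per SNP. Pedigree links then
    overwrite the second member (and, for full siblings, both members) with
    genotypes transmitted from simulated parents, so every individual keeps
    the Binomial(2, p) marginal.
    """
    inds = cohort.individuals()
    for _, g in inds:
        if g not in freqs.pops:
            raise KeyError(f"group {g!r} not in frequency table")
    n_snp = freqs.freqs.shape[1]
    values = np.empty((len(inds), n_snp), dtype=np.int8)
    index = {}
    for i, (name, g) in enumerate(inds):
        rng = stream(seed, "geno", g, name)
        values[i] = rng.binomial(2, freqs.freq(g)).astype(np.int8)
        index[name] = i

    group_of = {n: g for n, g in inds}
    for a, bname, rel in cohort.pedigree:
        p = freqs.freq(group_of[a])
        rng = stream(seed, "pedigree", a, bname, rel)
        ia, ib = index[a], index[bname]
        if rel == "duplicate":
            values[ib] = values[ia]
        elif rel == "parent_offspring":
            values[ib] = _transmit(values[ia], rng) + rng.binomial(1, p).astype(
                np.int8
            )
        elif rel == "full_sib":
            father = rng.binomial(2, p).astype(np.int8)
            mother = rng.binomial(2, p).astype(np.int8)
            values[ia] = _transmit(father, rng) + _transmit(mother, rng)
            values[ib] = _transmit(father, rng) + _transmit(mother, rng)
        elif rel == "second_degree":
            shared = rng.binomial(2, p).astype(np.int8)
            values[ia] = _transmit(shared, rng) + rng.binomial(1, p).astype(
                np.int8
            )
            values[ib] = _transmit(shared, rng) + rng.binomial(1, p).astype(
                np.int8
            )

    if panel is None:
        panel = SNPPanel.uniform(n_snp)
    if len(panel) != n_snp:
        raise ValueError("panel size does not match frequency table")
    return GenotypeMatrix(
        panel, [n for n, _ in inds], values, ploidy=2,
        groups={n: g for n, g in inds},
    )


def random_allele_calls(
    genotypes: GenotypeMatrix, seed: int, library: str = "L1"
) -> GenotypeMatrix:
    """Idealized pseudo-haploid calls: one allele per site drawn uniformly.

    Equivalent to pseudo-haploid calling on an error-free pileup at depth 1;
    heterozygous sites yield the alternative allele with probability 1/2.
    """
    vals = np.empty_like(genotypes.values)
    for i, ind in enumerate(genotypes.individuals):
        rng = stream(seed, "pscall", ind, library)
        g = genotypes.values[i]
        vals[i] = np.where(
            g == MISSING, MISSING,
            (rng.random(g.shape) < g / 2.0).astype(np.int8),
        )
    return GenotypeMatrix(
        genotypes.panel, list(genotypes.individuals), vals, ploidy=1,
        groups=dict(genotypes.groups),
    )


# ---------------------------------------------------------------------------
# pileups with damage
# ---------------------------------------------------------------------------

PILEUP_COLUMNS = [
    "individual", "library", "chromosome", "position", "base",
    "base_quality", "mapping_quality", "strand", "read_position",
    "read_length", "library_type",
]


def simulate_pileup(
    genotypes: GenotypeMatrix,
    cohort: CohortSpec,
    panel: SNPPanel,
    read_len: int = 70,
    seed: int = 0,
    n_libraries: int = 1,
    low_quality_fraction: float = 0.1,
) -> pd.DataFrame:
    """Per-site read pileups with coverage, quality, strand, and damage.

    Depth is Poisson(lambda) per individual per site; each read carries one
    of the individual's true alleles. Terminal deamination: with probability
    ``damage_rate``, a C within 5 bp of either read end on a plus-strand
    read is emitted as T, and a G on a minus-strand read as A (the
    reference-strand image of the read's own C->T). Base qualities fall
    below 30 for a ``low_quality_fraction`` of reads, mapping qualities
    below 30 for an equal fraction.
    """
    if read_len <= 10:
        raise ValueError("read_len must be > 10")
    rows = {c: [] for c in PILEUP_COLUMNS}
    for i, ind in enumerate(genotypes.individuals):
        lam = cohort.depth_of(ind)
        if lam < 0:
            raise ValueError("mean depth must be >= 0")
        delta = cohort.damage_of(ind)
        lib_type = cohort.library_type_of(ind)
        for lib_i in range(n_libraries):
            lib = f"{ind}_L{lib_i + 1}"
            rng = stream(seed, "pileup", ind, lib)
            depth = rng.poisson(lam, size=len(panel))
            total = int(depth.sum())
            if total == 0:
                continue
            site_idx = np.repeat(np.arange(len(panel)), depth)
            g = genotypes.values[i][site_idx]
            keep = g != MISSING
            site_idx, g = site_idx[keep], g[keep]
            m = len(site_idx)
            if m == 0:
                continue
            is_alt = rng.random(m) < g / 2.0
            base = np.where(is_alt, panel.alt[site_idx], panel.ref[site_idx])
            strand = np.where(rng.random(m) < 0.5, "+", "-")
            read_pos = rng.integers(1, read_len + 1, size=m)
            bq = np.where(
                rng.random(m) < low_quality_fraction,
                rng.integers(15, 30, size=m),
                rng.integers(30, 42, size=m),
            )
            mq = np.where(
                rng.random(m) < low_quality_fraction,
                rng.integers(0, 30, size=m),
                rng.integers(30, 61, size=m),
            )
            if delta > 0:
                terminal = (read_pos <= 5) | (read_pos > read_len - 5)
                hit = terminal & (rng.random(m) < delta)
                base = np.where(hit & (strand == "+") & (base == "C"), "T", base)
                base = np.where(hit & (strand == "-") & (base == "G"), "A", base)
            rows["individual"].append(np.full(m, ind))
            rows["library"].append(np.full(m, lib))
            rows["chromosome"].append(panel.chrom[site_idx])
            rows["position"].append(panel.pos[site_idx])
            rows["base"].append(base)
            rows["base_quality"].append(bq)
            rows["mapping_quality"].append(mq)
            rows["strand"].append(strand)
            rows["read_position"].append(read_pos)
            rows["read_length"].append(np.full(m, read_len))
            rows["library_type"].append(np.full(m, lib_type))
    if not rows["individual"]:
        return pd.DataFrame({c: [] for c in PILEUP_COLUMNS})
    return pd.DataFrame(
        {c: np.concatenate(rows[c]) for c in PILEUP_COLUMNS}
    ).astype({"position": np.int64, "base_quality": np.int64,
              "mapping_quality": np.int64, "read_position": np.int64,
              "read_length": np.int64})


# ---------------------------------------------------------------------------
# admixed chromosomes
# ---------------------------------------------------------------------------


def _simulate_haplotype_states(
    gpos: np.ndarray, alpha: float, g: float, rng
) -> tuple[np.ndarray, list[tuple[float, float, int]]]:
    """Markov local ancestry along one chromosome.

    Switch events arrive as a Poisson process of rate ``g`` per Morgan; at
    each event the state redraws Bernoulli(alpha) (1 = source1). Returns
    per-SNP states and merged (start_M, end_M, state) tracts.
    """
    lo, hi = float(gpos[0]), float(gpos[-1])
    length = hi - lo
    n_events = rng.poisson(g * length) if length > 0 else 0
    breaks = np.sort(rng.uniform(lo, hi, size=n_events))
    seg_states = (rng.random(n_events + 1) < alpha).astype(np.int8)
    states = seg_states[np.searchsorted(breaks, gpos, side="right")]
    # merge consecutive equal-state segments into tracts
    bounds = np.concatenate(([lo], breaks, [hi]))
    tracts = []
    for s, e, st in zip(bounds[:-1], bounds[1:], seg_states):
        if tracts and tracts[-1][2] == st:
            tracts[-1] = (tracts[-1][0], float(e), int(st))
        else:
            tracts.append((float(s), float(e), int(st)))
    return states, tracts


def simulate_admixed_genotypes(
    spec: AdmixedSampleSpec,
    freqs: FreqTable,
    panel: SNPPanel,
    seed: int,
) -> tuple[GenotypeMatrix, np.ndarray, list]:
    """Diploid genotypes of an admixed sample plus true local ancestry.

    Returns (genotypes, hap_states, tracts): ``hap_states`` is a
    (2 * n_individuals, n_snps) matrix of per-haplotype source indicators
    (1 = source1), ``tracts`` the list of merged ancestry tracts per
    haplotype per chromosome as (chrom, start_M, end_M, state).
    """
    for s in (spec.source1, spec.source2):
        if s not in freqs.pops:
            raise KeyError(f"source {s!r} not in frequency table")
    p1, p2 = freqs.freq(spec.source1), freqs.freq(spec.source2)
    n = spec.n_individuals
    hap_states = np.empty((2 * n, len(panel)), dtype=np.int8)
    values = np.zeros((n, len(panel)), dtype=np.int8)
    all_tracts = []
    chrom_masks = [(c, panel.chrom_mask(c)) for c in panel.chromosomes]
    for i in range(n):
        for h in range(2):
            rng = stream(seed, "admix", i, h)
            row = 2 * i + h
            for c, mask in chrom_masks:
                gp = panel.gpos[mask]
                if np.any(np.diff(gp) < 0):
                    raise ValueError("genetic map must be non-decreasing")
                states, tracts = _simulate_haplotype_states(
                    gp, spec.alpha, spec.generations, rng
                )
                hap_states[row, mask] = states
                all_tracts.extend((c, s, e, st) for s, e, st in tracts)
            p_local = np.where(hap_states[row] == 1, p1, p2)
            values[i] += (rng.random(len(panel)) < p_local).astype(np.int8)
    gm = GenotypeMatrix(
        panel, [f"admixed{i}" for i in range(n)], values, ploidy=2,
        groups={f"admixed{i}": "admixed" for i in range(n)},
    )
    return gm, hap_states, all_tracts
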