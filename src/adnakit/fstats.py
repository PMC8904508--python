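"""f-statistics with weighted block jackknife standard errors.

f2, f3 and f4 are moment statistics of allele-frequency differences
(Patterson-style): per SNP,

    f2(A,B)   = (a - b)^2        - a(1-a)/(nA-1) - b(1-b)/(nB-1)
    f3(C;A,B) = (c - a)(c - b)   - c(1-c)/(nC-1)
    f4(A,B;C,D) = (a - b)(c - d)

with hats on sample frequencies and the subtracted terms the finite-sample
bias corrections (applied when ``corrected``; f4 needs none). Aggregates are
means over SNPs at which every argument population has data; standard
errors come from a weighted delete-one-block jackknife over contiguous
5 cM blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .matrix import MISSING, GenotypeMatrix
from .panel import SNPPanel

__all__ = [
    "AlleleCounts",
    "BlockPartition",
    "FStatResult",
    "f2",
    "f3",
    "f4",
    "fstat",
    "block_jackknife",
]


@dataclass
class AlleleCounts:
    """Per-population derived-allele counts x out of n called alleles."""

    pops: list[str]
    x: np.ndarray  # (n_pops, n_snps) derived counts (float to admit freqs)
    n: np.ndarray  # (n_pops, n_snps) total called alleles
    haploid_pops: frozenset = frozenset()  # pops from pseudo-haploid calls

    def __post_init__(self):
        self.haploid_pops = frozenset(self.haploid_pops)
        self.x = np.asarray(self.x, dtype=np.float64)
        self.n = np.asarray(self.n, dtype=np.float64)
        if self.x.shape != self.n.shape or self.x.shape[0] != len(self.pops):
            raise ValueError("x/n shapes do not match pops")
        if np.any(self.n < 0) or np.any((self.x < 0) | (self.x > self.n)):
            raise ValueError("need 0 <= x <= n")

    @property
    def n_snps(self) -> int:
        return self.x.shape[1]

    def _row(self, pop: str) -> int:
        try:
            return self.pops.index(pop)
        except ValueError:
            raise KeyError(f"population {pop!r} not in counts") from None

    def freq(self, pop: str) -> np.ndarray:
        """Sample frequency x/n, NaN where n = 0."""
        i = self._row(pop)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.n[i] > 0, self.x[i] / self.n[i], np.nan)

    def size(self, pop: str) -> np.ndarray:
        return self.n[self._row(pop)]

    @classmethod
    def from_matrix(
        cls, matrix: GenotypeMatrix, groups: dict[str, list[str]] | None = None
    ) -> "AlleleCounts":
        """Tally alt alleles by population (haploid calls count 1, diploid 2)."""
        if groups is None:
            groups = {}
            for ind in matrix.individuals:
                groups.setdefault(matrix.group_of(ind), []).append(ind)
        pops = list(groups)
        x = np.zeros((len(pops), len(matrix.panel)))
        n = np.zeros_like(x)
        for k, pop in enumerate(pops):
            rows = [matrix.individuals.index(i) for i in groups[pop]]
            sub = matrix.values[rows]
            present = sub != MISSING
            x[k] = np.where(present, sub, 0).sum(axis=0)
            n[k] = present.sum(axis=0) * matrix.ploidy
        haploid = frozenset(pops) if matrix.ploidy == 1 else frozenset()
        return cls(pops, x, n, haploid)

    @classmethod
    def from_frequencies(cls, pops: list[str], freqs: np.ndarray) -> "AlleleCounts":
        """Population frequencies treated as exact (n = 1 allele unit).

        Suitable only for uncorrected statistics; corrected estimators
        require real allele counts.
        """
        freqs = np.asarray(freqs, dtype=np.float64)
        return cls(list(pops), freqs, np.ones_like(freqs))


@dataclass
class BlockPartition:
    """Assignment of every SNP to a contiguous genetic-distance block."""

    block_ids: np.ndarray  # int per SNP
    span_cM: float = 5.0

    def __post_init__(self):
        self.block_ids = np.asarray(self.block_ids, dtype=np.int64)
        # relabel to consecutive 0..g-1 preserving order
        _, self.block_ids = np.unique(self.block_ids, return_inverse=True)

    @property
    def n_blocks(self) -> int:
        return int(self.block_ids.max()) + 1 if len(self.block_ids) else 0

    @property
    def sizes(self) -> np.ndarray:
        return np.bincount(self.block_ids, minlength=self.n_blocks)

    @classmethod
    def from_panel(cls, panel: SNPPanel, span_cM: float = 5.0) -> "BlockPartition":
        """Contiguous blocks of ``span_cM`` in genetic distance per chromosome.

        SNPs without a genetic position (NaN) fall back to physical position
        at 1 cM/Mb.
        """
        ids = np.zeros(len(panel), dtype=np.int64)
        offset = 0
        for c in panel.chromosomes:
            m = panel.chrom_mask(c)
            g = panel.gpos[m].copy()
            nan = ~np.isfinite(g)
            g[nan] = panel.pos[m][nan] / 1e8  # 1 cM/Mb in Morgans
            rel = (g - g.min()) * 100.0 / span_cM
            local = np.floor(rel).astype(np.int64)
            ids[m] = offset + local
            offset = ids[m].max() + 1
        return cls(ids, span_cM)


@dataclass
class FStatResult:
    kind: str
    pops: tuple[str, ...]
    estimate: float
    se: float
    n_snps: int
    n_blocks: int
    block_sums: np.ndarray = field(repr=False, default=None)
    block_counts: np.ndarray = field(repr=False, default=None)

    @property
    def z(self) -> float:
        return self.estimate / self.se if self.se > 0 else np.inf


# ---------------------------------------------------------------------------
# per-SNP values
# ---------------------------------------------------------------------------


def _freqs(counts: AlleleCounts, pops, corrected_pops=()):
    fs, ns = [], []
    for p in pops:
        fs.append(counts.freq(p))
        ns.append(counts.size(p))
    valid = np.ones(counts.n_snps, dtype=bool)
    for p, n in zip(pops, ns):
        need = 2 if p in corrected_pops else 1
        valid &= n >= need
    return fs, ns, valid


def f2_per_snp(counts: AlleleCounts, A: str, B: str, corrected: bool = True):
    corr_pops = (A, B) if corrected else ()
    (a, b), (na, nb), valid = _freqs(counts, (A, B), corr_pops)
    with np.errstate(invalid="ignore", divide="ignore"):
        v = (a - b) ** 2
        if corrected:
            v = v - a * (1 - a) / (na - 1) - b * (1 - b) / (nb - 1)
    return v, valid


def f3_per_snp(counts: AlleleCounts, C: str, A: str, B: str,
               corrected: bool = True):
    if C in counts.haploid_pops:
        corrected = False  # the bias correction is undefined for 1 draw/ind
    corr_pops = (C,) if corrected else ()
    (c, a, b), (nc, na, nb), valid = _freqs(counts, (C, A, B), corr_pops)
    with np.errstate(invalid="ignore", divide="ignore"):
        v = (c - a) * (c - b)
        if corrected:
            v = v - c * (1 - c) / (nc - 1)
    return v, valid


def f4_per_snp(counts: AlleleCounts, A: str, B: str, C: str, D: str):
    (a, b, c, d), _, valid = _freqs(counts, (A, B, C, D))
    with np.errstate(invalid="ignore"):
        v = (a - b) * (c - d)
    return v, valid


# ---------------------------------------------------------------------------
# jackknife
# ---------------------------------------------------------------------------


def block_jackknife(
    values: np.ndarray,
    partition: BlockPartition,
    valid: np.ndarray | None = None,
    weights: np.ndarray | None = None,
) -> tuple[float, float, np.ndarray, np.ndarray]:
    """Weighted delete-one-block jackknife of a mean over SNPs.

    Blocks are weighted by their (weighted) SNP counts m_j; the variance is
    the weighted jackknife formula (pseudovalues tau_j = h_j theta - (h_j-1)
    theta_(-j) with h_j = n/m_j), which reduces to the delete-1 jackknife
    for equal block sizes. Returns (estimate, se, block_sums, block_counts).
    """
    values = np.asarray(values, dtype=np.float64)
    if valid is None:
        valid = np.isfinite(values)
    else:
        valid = valid & np.isfinite(values)
    if weights is None:
        weights = np.ones_like(values)
    ids = partition.block_ids
    g_all = partition.n_blocks
    w = np.where(valid, weights, 0.0)
    wv = np.where(valid, weights * values, 0.0)
    block_sums = np.bincount(ids, weights=wv, minlength=g_all)
    block_counts = np.bincount(ids, weights=w, minlength=g_all)
    nonempty = block_counts > 0
    if nonempty.sum() < 2:
        raise ValueError(
            "need at least 2 non-empty blocks for a jackknife "
            "(genetic span too small?)"
        )
    S, N = block_sums[nonempty], block_counts[nonempty]
    tot_s, tot_n = S.sum(), N.sum()
    theta = tot_s / tot_n
    theta_loo = (tot_s - S) / (tot_n - N)
    g = len(S)
    h = tot_n / N
    theta_j = g * theta - ((1 - N / tot_n) * theta_loo).sum()
    tau = h * theta - (h - 1) * theta_loo
    var = np.sum((tau - theta_j) ** 2 / (h - 1)) / g
    return float(theta), float(np.sqrt(var)), block_sums, block_counts


def fstat(
    kind: str,
    counts: AlleleCounts,
    pops: tuple[str, ...],
    partition: BlockPartition,
    corrected: bool = True,
) -> FStatResult:
    """Blocked f-statistic with jackknife SE and z-score."""
    if kind == "f2":
        values, valid = f2_per_snp(counts, *pops, corrected=corrected)
    elif kind == "f3":
        values, valid = f3_per_snp(counts, *pops, corrected=corrected)
    elif kind == "f4":
        values, valid = f4_per_snp(counts, *pops)
    else:
        raise ValueError(f"unknown statistic {kind!r}")
    if not valid.any():
        raise ValueError("no overlapping SNPs for this statistic")
    est, se, bs, bc = block_jackknife(values, partition, valid)
    return FStatResult(
        kind, tuple(pops), est, se, int(valid.sum()),
        int((bc > 0).sum()), bs, bc,
    )


def batch_fstats(
    kind: str,
    counts: AlleleCounts,
    poplist: str | list[str],
    partition: BlockPartition,
    corrected: bool = True,
) -> list[FStatResult]:
    """Run one statistic over a population-list file.

    ``poplist`` is a path or list of lines in the whitespace-separated
    convention of the classic batch drivers: one population tuple per line
    (3 names for f3 as C A B, 4 for f4, 2 for f2); blank lines and
    ``#`` comments are skipped.
    """
    if isinstance(poplist, (str,)) and "\n" not in poplist:
        with open(poplist) as fh:
            lines = fh.readlines()
    elif isinstance(poplist, str):
        lines = poplist.splitlines()
    else:
        lines = list(poplist)
    arity = {"f2": 2, "f3": 3, "f4": 4}[kind]
    out = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.split("#")[0].strip()
        if not line:
            continue
        pops = tuple(line.split())
        if len(pops) != arity:
            raise ValueError(
                f"line {lineno}: {kind} needs {arity} populations, "
                f"got {len(pops)}"
            )
        out.append(fstat(kind, counts, pops, partition, corrected=corrected))
    return out


def f2(counts, A, B, partition, corrected=True) -> FStatResult:
    return fstat("f2", counts, (A, B), partition, corrected)


def f3(counts, C, A, B, partition, corrected=True) -> FStatResult:
    """f3(C; A, B). The correction requires diploid-like counts in C;
    disable it (or it is meaningless) for pseudo-haploid targets."""
    return fstat("f3", counts, (C, A, B), partition, corrected)


def f4(counts, A, B, C, D, partition) -> FStatResult:
    return fstat("f4", counts, (A, B, C, D), partition, corrected=False)
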