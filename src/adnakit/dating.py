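"""Admixture dating from the decay of ancestry covariance with distance.

After a two-way admixture pulse g generations ago, local-ancestry
correlation between two loci d Morgans apart decays as exp(-g d). The
statistic: per SNP k the ancestry-informative weight w_k = p1_k - p2_k
(the source populations' allele-frequency difference) and per-individual
residual
r_k = g_k/2 - (p1_k + p2_k)/2; for every same-chromosome SNP pair the
across-individual covariance of residuals, weighted by w_k w_l, is
accumulated into genetic-distance bins. Fitting A exp(-g d) + c to the
binned curve estimates the admixture time g in generations, with a
leave-one-chromosome-out jackknife SE.

Bin width defaults to 1 cM and the fit extends to 1 Morgan (0.01 and 1.0
in the Morgan units of the classic implementations).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .matrix import MISSING, GenotypeMatrix
from .panel import SNPPanel

__all__ = ["DecayCurve", "DatesFit", "ancestry_covariance", "fit_decay"]


@dataclass
class DecayCurve:
    """Binned weighted ancestry covariance by genetic distance."""

    bin_left_cM: np.ndarray  # left edges, width = binsize
    binsize_cM: float
    values: np.ndarray  # per-bin mean weighted covariance
    n_pairs: np.ndarray  # per-bin pair counts
    chrom_sums: np.ndarray | None = None  # (n_chrom, n_bins) for jackknife
    chrom_counts: np.ndarray | None = None
    chromosomes: list | None = None

    @property
    def bin_centers_M(self) -> np.ndarray:
        return (self.bin_left_cM + self.binsize_cM / 2) / 100.0


@dataclass
class DatesFit:
    amplitude: float
    generations: float  # the decay rate per Morgan
    offset: float
    se: float  # jackknife SE of generations
    fit_window_cM: tuple[float, float]
    converged: bool = True
    n_bins: int = 0

    def years(self, generation_time: float) -> float:
        """Calendar conversion; a generation time must be given explicitly."""
        return self.generations * generation_time


def ancestry_covariance(
    target: GenotypeMatrix,
    ref1_freqs: np.ndarray,
    ref2_freqs: np.ndarray,
    panel: SNPPanel,
    binsize_cM: float = 1.0,
    max_dist_cM: float = 100.0,
) -> DecayCurve:
    """Weighted ancestry-covariance decay curve.

    ``target`` may be diploid genotypes or pseudo-haploid calls (which are
    scaled to {0, 2}); ``ref1_freqs``/``ref2_freqs`` are the two reference
    populations' allele frequencies over the panel. Bin i covers
    [i*binsize, (i+1)*binsize) cM. With a single target individual the
    uncentered residual product replaces the across-individual covariance.
    """
    p1 = np.asarray(ref1_freqs, dtype=float)
    p2 = np.asarray(ref2_freqs, dtype=float)
    if p1.shape != (len(panel),) or p2.shape != (len(panel),):
        raise ValueError("reference frequencies must cover the panel")
    if target.n_individuals < 1:
        raise ValueError("need at least one target individual")
    G = target.values.astype(float)
    if target.ploidy == 1:
        G = G * 2.0
    G[target.values == MISSING] = np.nan
    w = p1 - p2
    R = G / 2.0 - (p1 + p2) / 2.0  # (n_ind, n_snp)

    n_bins = int(np.ceil(max_dist_cM / binsize_cM))
    chroms = panel.chromosomes
    chrom_sums = np.zeros((len(chroms), n_bins))
    chrom_counts = np.zeros((len(chroms), n_bins), dtype=np.int64)
    n_ind = target.n_individuals

    for ci, c in enumerate(chroms):
        m = panel.chrom_mask(c)
        gp = panel.gpos[m] * 100.0  # cM
        Rc = R[:, m]
        wc = w[m]
        ok = np.all(np.isfinite(Rc), axis=0) & np.isfinite(wc)
        gp, Rc, wc = gp[ok], Rc[:, ok], wc[ok]
        s = len(gp)
        if s < 2:
            continue
        if n_ind >= 2:
            Rm = Rc - Rc.mean(axis=0, keepdims=True)
            C = (Rm.T @ Rm) / (n_ind - 1)
        else:
            C = Rc.T @ Rc
        W = np.outer(wc, wc) * C
        D = np.abs(gp[:, None] - gp[None, :])
        iu = np.triu_indices(s, k=1)
        d = D[iu]
        vals = W[iu]
        sel = (d > 0) & (d <= max_dist_cM)
        if not sel.any():
            continue
        bins = np.minimum((d[sel] / binsize_cM).astype(np.int64), n_bins - 1)
        chrom_sums[ci] += np.bincount(bins, weights=vals[sel], minlength=n_bins)
        chrom_counts[ci] += np.bincount(bins, minlength=n_bins)

    counts = chrom_counts.sum(axis=0)
    if counts.sum() == 0:
        raise ValueError("no SNP pairs within the distance range")
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(counts > 0, chrom_sums.sum(axis=0) / counts, np.nan)
    return DecayCurve(
        np.arange(n_bins) * binsize_cM, binsize_cM, values, counts,
        chrom_sums, chrom_counts, list(chroms),
    )


def _fit_exponential(
    d_M: np.ndarray, y: np.ndarray, starts=(5.0, 20.0, 50.0, 200.0)
) -> tuple[float, float, float, bool]:
    """Bounded least squares of y = A exp(-g d) + c, multi-start over g."""
    scale = max(float(np.max(np.abs(y))), 1e-30)

    def resid(params):
        A, g, c = params
        return (A * np.exp(-g * d_M) + c - y) / scale

    best, ok = None, False
    for g0 in starts:
        x0 = np.array([max(y[0] - y[-1], scale * 0.1), g0, float(y[-1])])
        try:
            res = least_squares(
                resid, x0,
                bounds=([0.0, 1e-6, -np.inf], [np.inf, np.inf, np.inf]),
                method="trf",
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
            ok = res.status > 0
    if best is None:
        return np.nan, np.nan, np.nan, False
    A, g, c = best.x
    return float(A), float(g), float(c), ok


def fit_decay(
    curve: DecayCurve, min_dist_cM: float = 0.05
) -> DatesFit:
    """Fit the exponential decay and jackknife the rate over chromosomes.

    Bins left of ``min_dist_cM`` are excluded (background LD contaminates
    short range); the decay rate is the admixture age in generations. The
    SE uses the weighted jackknife over leave-one-chromosome-out refits,
    with chromosome pair counts as weights.
    """
    centers_M = curve.bin_centers_M
    use = (
        (curve.bin_left_cM >= min_dist_cM)
        & (curve.n_pairs > 0)
        & np.isfinite(curve.values)
    )
    if use.sum() < 10:
        raise ValueError("need at least 10 usable bins to fit")
    d, y = centers_M[use], curve.values[use]
    A, g, c, ok = _fit_exponential(d, y)

    se = np.nan
    if curve.chrom_sums is not None and len(curve.chromosomes) >= 2:
        tot_s = curve.chrom_sums.sum(axis=0)
        tot_c = curve.chrom_counts.sum(axis=0)
        g_loo, m_w = [], []
        for ci in range(len(curve.chromosomes)):
            s = tot_s - curve.chrom_sums[ci]
            n = tot_c - curve.chrom_counts[ci]
            u = use & (n > 0)
            if u.sum() < 10:
                continue
            y_loo = s[u] / n[u]
            _, gj, _, _ = _fit_exponential(centers_M[u], y_loo)
            if np.isfinite(gj):
                g_loo.append(gj)
                m_w.append(curve.chrom_counts[ci].sum())
        if len(g_loo) >= 2:
            g_loo = np.array(g_loo)
            m_w = np.array(m_w, dtype=float)
            h = np.maximum(m_w.sum() / m_w, 1.0 + 1e-9)
            gg = len(g_loo)
            theta_j = gg * g - ((1 - m_w / m_w.sum()) * g_loo).sum()
            tau = h * g - (h - 1) * g_loo
            se = float(np.sqrt(np.sum((tau - theta_j) ** 2 / (h - 1)) / gg))
    return DatesFit(
        A, g, c, se, (float(d[0] * 100), float(d[-1] * 100)), ok,
        int(use.sum()),
    )
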