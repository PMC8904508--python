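"""Sliding-window outgroup-f3 selection scan.

f3(target; ancient, outgroup) quantifies how far the target population's
allele frequencies have moved relative to an ancient sample of the same
lineage and an outgroup. Computed in sliding windows (default 500 kb,
10 kb step), normalized by the target's window heterozygosity to remove
allele-frequency dependence, and converted to z-scores by resampling one
window per approximately-independent LD block.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from ._rng import stream
from .fstats import AlleleCounts
from .panel import SNPPanel

__all__ = [
    "WindowSpec",
    "window_scan",
    "ldblock_zscores",
    "call_candidates",
    "allele_frequency",
    "read_bed",
    "blocks_from_tiling",
]


@dataclass
class WindowSpec:
    """Sliding-window geometry and per-window inclusion minima."""

    size: int = 500_000
    step: int = 10_000
    min_snps: int = 250
    min_ancient_individuals: int = 15  # strictly-greater threshold

    def __post_init__(self):
        if self.step > self.size:
            raise ValueError("step must not exceed window size")
        if self.min_snps < 1 or self.min_ancient_individuals < 0:
            raise ValueError("minima must be >= 1")


def read_bed(path) -> pd.DataFrame:
    """BED intervals (0-based half-open) to 1-based half-open internally."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name"][: 4],
        dtype={0: str},
    )
    out = pd.DataFrame(
        {"chrom": df["chrom"].astype(str), "start": df["start"] + 1,
         "end": df["end"] + 1}
    )
    if "name" in df.columns and df["name"].notna().any():
        out["name"] = df["name"]
    return out


def blocks_from_tiling(panel: SNPPanel, block_bp: int) -> pd.DataFrame:
    """Uniform LD-block tiling of each chromosome (1-based half-open)."""
    rows = []
    for c in panel.chromosomes:
        hi = int(panel.pos[panel.chrom_mask(c)].max())
        for s in range(0, hi + block_bp, block_bp):
            rows.append((c, s, s + block_bp))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def window_scan(
    counts: AlleleCounts,
    ancient_coverage: np.ndarray,
    panel: SNPPanel,
    spec: WindowSpec = WindowSpec(),
    target: str = "target",
    ancient: str = "ancient",
    outgroup: str = "outgroup",
) -> pd.DataFrame:
    """Per-window raw and heterozygosity-normalized f3 statistics.

    SNP inclusion: data in all three groups, segregating in target or
    outgroup, and strictly more than ``min_ancient_individuals`` ancient
    individuals covered (``ancient_coverage`` counts them per SNP; build it
    from calls or pileups under the convention of your choice). Windows
    with fewer than ``min_snps`` qualifying SNPs are emitted with absent
    statistics. Per-SNP: f3 = (c-a)(c-b) - c(1-c)/(n-1) and heterozygosity
    2c(1-c) n/(n-1) with c the target frequency from n called alleles.
    """
    ancient_coverage = np.asarray(ancient_coverage)
    if ancient_coverage.shape != (len(panel),):
        raise ValueError("ancient_coverage must align with the panel")
    c = counts.freq(target)
    a = counts.freq(ancient)
    b = counts.freq(outgroup)
    nC = counts.size(target)
    with np.errstate(invalid="ignore", divide="ignore"):
        f3 = (c - a) * (c - b) - c * (1 - c) / (nC - 1)
        het = 2 * c * (1 - c) * nC / (nC - 1)
    seg = ((c > 0) & (c < 1)) | ((b > 0) & (b < 1))
    include = (
        np.isfinite(f3) & np.isfinite(het) & seg
        & (nC >= 2)
        & (ancient_coverage > spec.min_ancient_individuals)
    )

    rows = []
    for chrom in panel.chromosomes:
        mask = panel.chrom_mask(chrom)
        pos = panel.pos[mask]
        inc = include[mask]
        f3c = np.where(inc, f3[mask], 0.0)
        hetc = np.where(inc, het[mask], 0.0)
        cum_f3 = np.concatenate([[0.0], np.cumsum(f3c)])
        cum_h = np.concatenate([[0.0], np.cumsum(hetc)])
        cum_n = np.concatenate([[0], np.cumsum(inc.astype(int))])
        hi = int(pos.max())
        starts = np.arange(0, hi + 1, spec.step)
        lo_idx = np.searchsorted(pos, starts, side="left")
        hi_idx = np.searchsorted(pos, starts + spec.size, side="left")
        n_in = cum_n[hi_idx] - cum_n[lo_idx]
        sum_f3 = cum_f3[hi_idx] - cum_f3[lo_idx]
        sum_h = cum_h[hi_idx] - cum_h[lo_idx]
        qual = n_in >= spec.min_snps
        with np.errstate(invalid="ignore", divide="ignore"):
            raw = np.where(qual, sum_f3 / np.maximum(n_in, 1), np.nan)
            hbar = np.where(qual, sum_h / np.maximum(n_in, 1), np.nan)
            norm = np.where(qual & (hbar > 0), raw / hbar, np.nan)
        rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom, "start": starts,
                    "end": starts + spec.size, "n_snps": n_in,
                    "raw_f3": raw, "het": hbar, "norm_f3": norm,
                }
            )
        )
    if not rows:
        raise ValueError("no windows could be formed")
    out = pd.concat(rows, ignore_index=True)
    if not np.isfinite(out["norm_f3"]).any():
        raise ValueError(
            "no window met the SNP minimum (window size below SNP spacing?)"
        )
    return out


def _assign_blocks(stats: pd.DataFrame, blocks: pd.DataFrame) -> pd.Series:
    """Block id per window by window start; uncovered -> nearest block."""
    ids = np.full(len(stats), -1, dtype=int)
    uncovered = 0
    for chrom, grp in stats.groupby("chrom", sort=False):
        blk = blocks[blocks["chrom"] == chrom].reset_index()
        if blk.empty:
            uncovered += len(grp)
            continue
        for wi, s in zip(grp.index, grp["start"]):
            hit = blk[(blk["start"] <= s) & (s < blk["end"])]
            if len(hit):
                ids[stats.index.get_loc(wi)] = hit["index"].iloc[0]
            else:
                uncovered += 1
                centers = (blk["start"] + blk["end"]) / 2
                ids[stats.index.get_loc(wi)] = blk["index"].iloc[
                    int(np.argmin(np.abs(centers - s)))
                ]
    if uncovered:
        import warnings

        warnings.warn(f"{uncovered} windows outside LD blocks; nearest used")
    return pd.Series(ids, index=stats.index)


def ldblock_zscores(
    stats: pd.DataFrame,
    blocks: pd.DataFrame,
    n_resamples: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """z-scores from one-window-per-LD-block resampling.

    Each resample draws one qualifying window per block and takes the mean
    and SD of the normalized statistic; mean and SD are averaged over
    ``n_resamples`` draws and z = (value - mean)/SD. All-equal values give
    SD 0 and a degenerate (NaN) z.
    """
    stats = stats.copy()
    stats["block"] = _assign_blocks(stats, blocks)
    qual = stats[np.isfinite(stats["norm_f3"])]
    groups = [
        grp["norm_f3"].to_numpy() for _, grp in qual.groupby("block", sort=True)
    ]
    if len(groups) < 20:
        raise ValueError(
            f"only {len(groups)} LD blocks with qualifying windows (< 20)"
        )
    rng = stream(seed, "ldblock")
    means, sds = np.empty(n_resamples), np.empty(n_resamples)
    for t in range(n_resamples):
        draw = np.array([g[rng.integers(0, len(g))] for g in groups])
        means[t] = draw.mean()
        sds[t] = draw.std(ddof=1)
    mu, sd = float(means.mean()), float(sds.mean())
    if sd == 0:
        stats["z"] = np.nan
        stats.attrs["degenerate"] = True
    else:
        stats["z"] = (stats["norm_f3"] - mu) / sd
        stats.attrs["degenerate"] = False
    stats.attrs["resample_mean"] = mu
    stats.attrs["resample_sd"] = sd
    return stats


def call_candidates(
    stats: pd.DataFrame,
    z_threshold: float = 4.0,
    genes: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Merge super-threshold windows into candidate regions.

    Overlapping windows with z > threshold coalesce; each region reports
    its span, its maximum-z window, and overlapping gene annotations.
    """
    hits = stats[np.isfinite(stats["z"]) & (stats["z"] > z_threshold)]
    regions = []
    for chrom, grp in hits.groupby("chrom", sort=False):
        grp = grp.sort_values("start")
        cur = None
        for _, w in grp.iterrows():
            if cur is not None and w["start"] < cur["end"]:
                cur["end"] = max(cur["end"], w["end"])
                if w["z"] > cur["max_z"]:
                    cur["max_z"] = w["z"]
                    cur["max_z_start"] = w["start"]
            else:
                if cur is not None:
                    regions.append(cur)
                cur = {
                    "chrom": chrom, "start": int(w["start"]),
                    "end": int(w["end"]), "max_z": float(w["z"]),
                    "max_z_start": int(w["start"]),
                }
        if cur is not None:
            regions.append(cur)
    out = pd.DataFrame(
        regions, columns=["chrom", "start", "end", "max_z", "max_z_start"]
    )
    labels = []
    for _, r in out.iterrows():
        if genes is None or genes.empty:
            labels.append("")
            continue
        hit = genes[
            (genes["chrom"] == r["chrom"])
            & (genes["start"] < r["end"])
            & (genes["end"] > r["start"])
        ]
        labels.append(",".join(hit.get("name", pd.Series(dtype=str)).astype(str)))
    out["genes"] = labels
    return out


def allele_frequency(
    derived: int, total: int, confidence: float = 0.95
) -> tuple[float, tuple[float, float], int]:
    """Derived-allele frequency with a Wilson score interval."""
    if total < 1:
        raise ValueError("no called alleles")
    freq = derived / total
    lo, hi = proportion_confint(derived, total, alpha=1 - confidence,
                                method="wilson")
    return freq, (float(lo), float(hi)), total
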