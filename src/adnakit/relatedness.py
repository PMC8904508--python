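"""Relatedness screening from pairwise mismatch rates (PMR).

For pseudo-haploid calls the expected mismatch rate between two call sets
is (1 - phi) * B, where phi is the kinship coefficient and B the cohort
baseline (the mean heterozygosity, ~the unrelated-pair PMR): duplicates sit
near B/2, first-degree relatives near 3B/4, second-degree near 7B/8.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from ._rng import stream
from .matrix import MISSING, GenotypeMatrix

__all__ = [
    "PMRResult",
    "pairwise_mismatch",
    "estimate_baseline",
    "classify_pairs",
    "merge_duplicates",
    "pmr_report",
    "KINSHIP",
]

# kinship coefficients by class
KINSHIP = {
    "duplicate": 0.5,
    "first_degree": 0.25,
    "second_degree": 0.125,
    "unrelated": 0.0,
}


@dataclass
class PMRResult:
    pair: tuple[str, str]
    n_overlap: int
    n_mismatch: int

    @property
    def pmr(self) -> float:
        return self.n_mismatch / self.n_overlap

    @property
    def se(self) -> float:
        p = self.pmr
        return float(np.sqrt(p * (1 - p) / self.n_overlap))


def pairwise_mismatch(
    calls: GenotypeMatrix, min_overlap: int = 3000
) -> tuple[list[PMRResult], list[tuple[str, str, int]]]:
    """PMR for every unordered pair with enough jointly covered SNPs.

    Returns (results, insufficient) where ``insufficient`` lists pairs whose
    overlap fell below ``min_overlap`` with their overlap counts.
    """
    if calls.n_individuals < 2:
        raise ValueError("need at least two call sets")
    vals = calls.values
    present = vals != MISSING
    results, insufficient = [], []
    for i in range(len(calls.individuals)):
        for j in range(i + 1, len(calls.individuals)):
            both = present[i] & present[j]
            n = int(both.sum())
            pair = (calls.individuals[i], calls.individuals[j])
            if n < min_overlap:
                insufficient.append((*pair, n))
                continue
            mism = int((vals[i][both] != vals[j][both]).sum())
            results.append(PMRResult(pair, n, mism))
    return results, insufficient


def estimate_baseline(
    pmr_results: list[PMRResult], cluster_gap: float = 0.03
) -> float:
    """Baseline B = median PMR of the largest (modal) cluster.

    Assumes most pairs are unrelated. Values are single-linkage clustered
    with a merge gap of ``cluster_gap`` (about half the duplicate/first-
    degree class separation at B ~ 0.24); the most populous cluster is
    taken as the unrelated mode.
    """
    if len(pmr_results) < 3:
        raise ValueError("need at least 3 pairs to estimate a baseline")
    values = np.array([r.pmr for r in pmr_results])
    if np.ptp(values) < 1e-12:
        return float(np.median(values))
    z = linkage(values.reshape(-1, 1), method="single")
    labels = fcluster(z, t=cluster_gap, criterion="distance")
    modal = np.bincount(labels).argmax()
    return float(np.median(values[labels == modal]))


def classify_pairs(
    pmr_results: list[PMRResult], baseline: float
) -> list[tuple[tuple[str, str], str, bool]]:
    """Nearest-expected-value classification of each pair.

    Class = argmin over phi of |pmr - (1 - phi) * B|, with decision
    boundaries at the midpoints {0.625B, 0.8125B, 0.9375B}. A pair within
    2 SE of two expected values is flagged ambiguous.
    """
    if not 0.0 < baseline < 1.0:
        raise ValueError("baseline must lie in (0, 1)")
    out = []
    classes = list(KINSHIP)
    expected = np.array([(1 - KINSHIP[c]) * baseline for c in classes])
    for r in pmr_results:
        dist = np.abs(r.pmr - expected)
        cls = classes[int(dist.argmin())]
        ambiguous = int((dist < 2 * r.se).sum()) >= 2
        out.append((r.pair, cls, ambiguous))
    return out


def merge_duplicates(
    calls: GenotypeMatrix,
    duplicate_groups: list[list[str]],
    seed: int = 0,
    pileup: pd.DataFrame | None = None,
    panel_kwargs: dict | None = None,
) -> GenotypeMatrix:
    """Collapse duplicate call sets into one column per individual.

    With a pileup available the merged calls are re-drawn from the pooled
    eligible reads of the group (the pool-and-recall route); otherwise each
    site draws uniformly from the group's non-missing calls. Group names
    become the first member's name.
    """
    flat = [m for grp in duplicate_groups for m in grp]
    if len(flat) != len(set(flat)):
        raise ValueError("duplicate groups overlap")
    for m in flat:
        if m not in calls.individuals:
            raise KeyError(f"unknown call set {m!r}")
    grouped = {grp[0]: list(grp) for grp in duplicate_groups}
    singles = [i for i in calls.individuals if i not in flat]
    out_names = singles + list(grouped)

    if pileup is not None:
        from .calling import call_pseudohaploid

        lib_to_ind = {}
        for name, members in grouped.items():
            for m in members:
                lib_to_ind[m] = name
        for s in singles:
            lib_to_ind[s] = s
        pooled = pileup.copy()
        # pileup rows are per library; remap the individual column to merged ids
        pooled["individual"] = pooled["library"].map(
            lambda l: lib_to_ind.get(l, lib_to_ind.get(str(l).rsplit("_L", 1)[0]))
        )
        merged, _ = call_pseudohaploid(
            pooled, calls.panel, seed=seed, unit="individual",
            **(panel_kwargs or {}),
        )
        return merged.subset_individuals(
            [n for n in out_names if n in merged.individuals]
        )

    n_snp = len(calls.panel)
    vals = np.full((len(out_names), n_snp), MISSING, dtype=np.int8)
    for r, name in enumerate(out_names):
        members = grouped.get(name, [name])
        rows = np.array([calls.individuals.index(m) for m in members])
        sub = calls.values[rows]
        present = sub != MISSING
        n_present = present.sum(axis=0)
        rng = stream(seed, "merge", name)
        pick = rng.integers(0, np.maximum(n_present, 1))
        order = np.cumsum(present, axis=0) - 1  # rank of each member's call
        chosen = np.full(n_snp, MISSING, dtype=np.int8)
        for k in range(len(members)):
            sel = present[k] & (order[k] == pick)
            chosen[sel] = sub[k][sel]
        chosen[n_present == 0] = MISSING
        vals[r] = chosen
    return GenotypeMatrix(
        calls.panel, out_names, vals, ploidy=1,
        groups={n: calls.groups.get(n, n) for n in out_names},
    )


def pmr_report(
    pmr_results: list[PMRResult], baseline: float
) -> pd.DataFrame:
    """TSV-ready relatedness report (pair, overlap, pmr, se, class, flags)."""
    classes = classify_pairs(pmr_results, baseline)
    return pd.DataFrame(
        {
            "indA": [r.pair[0] for r in pmr_results],
            "indB": [r.pair[1] for r in pmr_results],
            "n_overlap": [r.n_overlap for r in pmr_results],
            "n_mismatch": [r.n_mismatch for r in pmr_results],
            "pmr": [r.pmr for r in pmr_results],
            "se": [r.se for r in pmr_results],
            "class": [c for _, c, _ in classes],
            "ambiguous": [a for _, _, a in classes],
        }
    )
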