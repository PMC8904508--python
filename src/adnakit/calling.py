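"""Pseudo-haploid genotype calling from read pileups.

One random high-quality base per site stands in for a genotype — the
standard treatment of low-coverage ancient DNA. Quality gates (base and
mapping quality >= 30), end trimming (no base within 5 bp of a read end),
and the single-strand rule (C/T sites from minus-strand reads only, G/A
sites from plus-strand reads only, which dodges terminal deamination)
mirror common aDNA practice.

The random draw at each site is keyed by (seed, chromosome, position,
calling unit), so calls are stable under pileup row permutation and SNP
subsetting.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._rng import stream
from .matrix import MISSING, GenotypeMatrix
from .panel import SNPPanel

__all__ = ["call_pseudohaploid", "eligible_reads"]

MODES = ("double_strand", "single_strand")

_CANONICAL_SORT = [
    "library", "strand", "read_position", "base",
    "base_quality", "mapping_quality",
]


def eligible_reads(
    pileup: pd.DataFrame,
    panel: SNPPanel,
    mode: str | None = None,
    min_base_quality: int = 30,
    min_map_quality: int = 30,
    end_trim: int = 5,
) -> tuple[pd.DataFrame, dict]:
    """Annotate pileup rows with panel indices and apply eligibility gates.

    Returns the eligible subset (with ``_site`` and ``_is_alt`` columns) and
    a dictionary of filter counts. ``mode=None`` takes each read's own
    ``library_type``; an explicit mode overrides it for all reads.
    """
    if mode is not None and mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    counts = {
        "total": len(pileup), "off_panel": 0, "low_base_quality": 0,
        "low_map_quality": 0, "end_trimmed": 0, "non_allelic": 0,
        "wrong_strand": 0, "eligible": 0,
    }
    if not len(pileup):
        return pileup.assign(_site=[], _is_alt=[]), counts

    panel_df = pd.DataFrame(
        {"chromosome": panel.chrom, "position": panel.pos,
         "_site": np.arange(len(panel)), "_ref": panel.ref, "_alt": panel.alt}
    )
    df = pileup.merge(panel_df, on=["chromosome", "position"], how="left")
    on_panel = df["_site"].notna()
    counts["off_panel"] = int((~on_panel).sum())
    df = df[on_panel].copy()
    df["_site"] = df["_site"].astype(int)

    bq_ok = df["base_quality"] >= min_base_quality
    mq_ok = df["mapping_quality"] >= min_map_quality
    not_terminal = (df["read_position"] > end_trim) & (
        df["read_position"] <= df["read_length"] - end_trim
    )
    allelic = (df["base"] == df["_ref"]) | (df["base"] == df["_alt"])

    eff_mode = df["library_type"] if mode is None else pd.Series(
        mode, index=df.index
    )
    allele_set = df["_ref"] + df["_alt"]
    is_ct = allele_set.isin(["CT", "TC"])
    is_ga = allele_set.isin(["GA", "AG"])
    strand_ok = ~(
        (eff_mode == "single_strand")
        & ((is_ct & (df["strand"] != "-")) | (is_ga & (df["strand"] != "+")))
    )

    counts["low_base_quality"] = int((~bq_ok).sum())
    counts["low_map_quality"] = int((bq_ok & ~mq_ok).sum())
    counts["end_trimmed"] = int((bq_ok & mq_ok & ~not_terminal).sum())
    counts["non_allelic"] = int((bq_ok & mq_ok & not_terminal & ~allelic).sum())
    counts["wrong_strand"] = int(
        (bq_ok & mq_ok & not_terminal & allelic & ~strand_ok).sum()
    )
    keep = bq_ok & mq_ok & not_terminal & allelic & strand_ok
    out = df[keep].copy()
    out["_is_alt"] = (out["base"] == out["_alt"]).astype(np.int8)
    counts["eligible"] = len(out)
    return out, counts


def call_pseudohaploid(
    pileup: pd.DataFrame,
    panel: SNPPanel,
    mode: str | None = None,
    min_base_quality: int = 30,
    min_map_quality: int = 30,
    end_trim: int = 5,
    seed: int = 0,
    unit: str = "individual",
) -> tuple[GenotypeMatrix, dict]:
    """Draw one eligible read per site per calling unit.

    ``unit="individual"`` pools all of an individual's libraries before the
    draw (the default); ``unit="library"`` calls each library separately,
    producing one matrix row per library (useful for duplicate screening).
    Sites with no eligible read are MISSING. Returns (calls, filter counts).
    """
    if unit not in ("individual", "library"):
        raise ValueError(f"unknown calling unit {unit!r}")
    elig, counts = eligible_reads(
        pileup, panel, mode, min_base_quality, min_map_quality, end_trim
    )
    if len(pileup):
        units = sorted(pileup[unit].astype(str).unique())
        ind_of = (
            dict(zip(pileup[unit].astype(str), pileup["individual"].astype(str)))
            if unit == "library"
            else {u: u for u in units}
        )
    else:
        units, ind_of = [], {}
    vals = np.full((len(units), len(panel)), MISSING, dtype=np.int8)
    row_of = {u: i for i, u in enumerate(units)}

    if len(elig):
        elig = elig.sort_values(_CANONICAL_SORT, kind="mergesort")
        for (u, site), grp in elig.groupby([elig[unit].astype(str), "_site"],
                                           sort=True):
            rng = stream(seed, "call", panel.chrom[site], int(panel.pos[site]), u)
            pick = int(rng.integers(0, len(grp)))
            vals[row_of[u], site] = grp["_is_alt"].iloc[pick]

    matrix = GenotypeMatrix(
        panel, units, vals, ploidy=1,
        groups={u: ind_of[u] for u in units},
    )
    return matrix, counts
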