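"""Readers and writers for EIGENSTRAT trios, pileup TSVs, and panel merging.

EIGENSTRAT layout: ``.geno`` holds one line per SNP with one character per
individual counting copies of the *reference* allele (9 = missing); ``.snp``
holds fixed-width columns (id, chromosome, genetic position in Morgans,
physical position, ref, alt); ``.ind`` holds (id, sex, population).
Internal matrices count *alternative* alleles, so writer and reader both
apply ``ploidy - value`` and any matrix round-trips exactly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import MISSING, GenotypeMatrix
from .panel import SNPPanel
from .simulate import PILEUP_COLUMNS

__all__ = [
    "write_eigenstrat",
    "read_eigenstrat",
    "write_pileup",
    "read_pileup",
    "validate_pileup",
    "merge_panels",
    "FormatError",
]


class FormatError(ValueError):
    """Malformed file content (with the offending line number when known)."""


# ---------------------------------------------------------------------------
# EIGENSTRAT
# ---------------------------------------------------------------------------


def write_eigenstrat(prefix: str | Path, matrix: GenotypeMatrix,
                     sex: dict[str, str] | None = None) -> None:
    """Write ``prefix``.geno/.snp/.ind from a genotype matrix."""
    prefix = Path(prefix)
    panel = matrix.panel
    with open(f"{prefix}.snp", "w") as fh:
        for i in range(len(panel)):
            fh.write(
                f"{panel.ids[i]:>15} {panel.chrom[i]:>4} "
                f"{panel.gpos[i]:>12.8f} {panel.pos[i]:>12} "
                f"{panel.ref[i]} {panel.alt[i]}\n"
            )
    with open(f"{prefix}.ind", "w") as fh:
        for ind in matrix.individuals:
            s = (sex or {}).get(ind, "U")
            fh.write(f"{ind:>15} {s} {matrix.group_of(ind):>15}\n")
    # geno: ref-allele counts, columns = individuals
    vals = matrix.values
    ref_counts = np.where(vals == MISSING, 9, matrix.ploidy - vals)
    chars = ref_counts.astype(np.uint8) + ord("0")
    with open(f"{prefix}.geno", "wb") as fh:
        for j in range(vals.shape[1]):
            fh.write(chars[:, j].tobytes() + b"\n")


def read_eigenstrat(
    prefix: str | Path, ploidy: int = 2
) -> tuple[SNPPanel, GenotypeMatrix, pd.DataFrame]:
    """Read an EIGENSTRAT trio; returns (panel, matrix, individual metadata).

    ``ploidy=1`` interprets genotypes as pseudo-haploid {0,1,9} calls.
    """
    prefix = Path(prefix)
    snp = pd.read_csv(
        f"{prefix}.snp", sep=r"\s+", header=None,
        names=["id", "chrom", "gpos", "pos", "ref", "alt"],
        dtype={"chrom": str},
    )
    panel = SNPPanel(
        snp["chrom"].to_numpy(), snp["pos"].to_numpy(),
        snp["gpos"].to_numpy(), snp["ref"].to_numpy(),
        snp["alt"].to_numpy(), snp["id"].to_numpy(),
    )
    ind = pd.read_csv(
        f"{prefix}.ind", sep=r"\s+", header=None,
        names=["id", "sex", "population"], dtype=str,
    )
    n_ind = len(ind)
    rows = []
    with open(f"{prefix}.geno", "rb") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if len(line) != n_ind:
                raise FormatError(
                    f"{prefix}.geno line {lineno}: expected {n_ind} "
                    f"genotypes, found {len(line)}"
                )
            rows.append(np.frombuffer(line, dtype=np.uint8) - ord("0"))
    if len(rows) != len(panel):
        raise FormatError(
            f"{prefix}.geno has {len(rows)} SNP lines, .snp has {len(panel)}"
        )
    ref_counts = np.array(rows, dtype=np.int16).T  # individuals x snps
    bad = (ref_counts != 9) & ((ref_counts < 0) | (ref_counts > ploidy))
    if np.any(bad):
        raise FormatError(f"{prefix}.geno contains values outside 0..{ploidy},9")
    vals = np.where(ref_counts == 9, MISSING, ploidy - ref_counts).astype(np.int8)
    matrix = GenotypeMatrix(
        panel, ind["id"].tolist(), vals, ploidy=ploidy,
        groups=dict(zip(ind["id"], ind["population"])),
    )
    return panel, matrix, ind


# ---------------------------------------------------------------------------
# pileup TSV
# ---------------------------------------------------------------------------


def validate_pileup(pileup: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PILEUP_COLUMNS if c not in pileup.columns]
    if missing:
        raise FormatError(f"pileup lacks columns {missing}")
    if len(pileup):
        if not pileup["base"].isin(list("ACGT")).all():
            raise FormatError("pileup bases outside {A,C,G,T}")
        if (pileup["base_quality"] < 0).any() or (
            pileup["mapping_quality"] < 0
        ).any():
            raise FormatError("negative quality in pileup")
        bad_pos = (pileup["read_position"] < 1) | (
            pileup["read_position"] > pileup["read_length"]
        )
        if bad_pos.any():
            raise FormatError("read_position outside [1, read_length]")
    return pileup


def write_pileup(path: str | Path, pileup: pd.DataFrame) -> None:
    validate_pileup(pileup)[PILEUP_COLUMNS].to_csv(path, sep="\t", index=False)


def read_pileup(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    return validate_pileup(df)


# ---------------------------------------------------------------------------
# merging datasets
# ---------------------------------------------------------------------------


def merge_panels(
    datasets: list[tuple[SNPPanel, GenotypeMatrix]],
    drop_strand_ambiguous: bool = True,
) -> tuple[SNPPanel, list[GenotypeMatrix], dict]:
    """Intersect datasets on (chromosome, position) and harmonize alleles.

    Sites present in every dataset are kept; A/T and C/G variants are
    dropped when ``drop_strand_ambiguous``. A dataset whose ref/alt are
    swapped relative to the first dataset has its genotypes flipped
    (``ploidy - g``); sites with irreconcilable allele pairs are dropped and
    counted. Returns (panel, matrices on that panel, counts dict).
    """
    if not datasets:
        raise ValueError("no datasets to merge")
    base_panel = datasets[0][0]
    keys = [(c, int(p)) for c, p in zip(base_panel.chrom, base_panel.pos)]
    shared = set(keys)
    for panel, _ in datasets[1:]:
        shared &= set(zip(panel.chrom, (int(p) for p in panel.pos)))
    counts = {"shared": len(shared), "allele_mismatch": 0,
              "strand_ambiguous": 0, "flipped": 0}

    indices = []  # per dataset: site index map
    for panel, _ in datasets:
        indices.append(panel.site_index())

    keep_rows = []
    flips = [[] for _ in datasets]  # per dataset: kept-site flip flags
    for key in keys:
        if key not in shared:
            continue
        i0 = indices[0][key]
        if drop_strand_ambiguous and base_panel.strand_ambiguous[i0]:
            counts["strand_ambiguous"] += 1
            continue
        ref0, alt0 = base_panel.ref[i0], base_panel.alt[i0]
        ok = True
        site_flips = [False]
        for d in range(1, len(datasets)):
            panel_d = datasets[d][0]
            idx = indices[d][key]
            r, a = panel_d.ref[idx], panel_d.alt[idx]
            if (r, a) == (ref0, alt0):
                site_flips.append(False)
            elif (r, a) == (alt0, ref0):
                site_flips.append(True)
                counts["flipped"] += 1
            else:
                counts["allele_mismatch"] += 1
                ok = False
                break
        if not ok:
            continue
        keep_rows.append(key)
        for d, f in enumerate(site_flips):
            flips[d].append(f)

    mask0 = np.zeros(len(base_panel), dtype=bool)
    for key in keep_rows:
        mask0[indices[0][key]] = True
    merged_panel = base_panel.subset(mask0)

    out_matrices = []
    for d, (panel_d, mat) in enumerate(datasets):
        idx = np.array([indices[d][key] for key in keep_rows], dtype=int)
        vals = mat.values[:, idx].copy()
        flip = np.array(flips[d], dtype=bool)
        nm = vals != MISSING
        vals[:, flip] = np.where(
            nm[:, flip], mat.ploidy - vals[:, flip], MISSING
        ).astype(np.int8)
        out_matrices.append(
            GenotypeMatrix(merged_panel, list(mat.individuals), vals,
                           mat.ploidy, dict(mat.groups))
        )
    counts["kept"] = len(keep_rows)
    return merged_panel, out_matrices, counts
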