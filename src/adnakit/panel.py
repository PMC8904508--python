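"""SNP marker panels.

A :class:`SNPPanel` is the marker list shared by every pipeline stage:
chromosome, physical position (1-based bp), genetic position (Morgans),
reference/alternative alleles, and a strand-ambiguity flag (A/T and C/G
variants, whose alleles are their own reverse complements).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SNPPanel", "COMPLEMENT"]

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class SNPPanel:
    """Sorted biallelic marker panel.

    Parameters
    ----------
    chrom : array of str
        Chromosome labels, sorted blockwise.
    pos : array of int
        1-based physical positions, sorted within chromosome.
    gpos : array of float
        Genetic positions in Morgans, non-decreasing within chromosome.
    ref, alt : array of single characters
        Reference and alternative alleles; ``ref != alt`` everywhere.
    ids : array of str, optional
        SNP identifiers; autogenerated as ``chr_pos`` when omitted.
    """

    chrom: np.ndarray
    pos: np.ndarray
    gpos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    ids: np.ndarray | None = field(default=None)

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom, dtype=str)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.gpos = np.asarray(self.gpos, dtype=np.float64)
        self.ref = np.asarray(self.ref, dtype=str)
        self.alt = np.asarray(self.alt, dtype=str)
        if self.ids is None:
            self.ids = np.array(
                [f"{c}_{p}" for c, p in zip(self.chrom, self.pos)], dtype=str
            )
        else:
            self.ids = np.asarray(self.ids, dtype=str)
        n = len(self.pos)
        for arr in (self.chrom, self.gpos, self.ref, self.alt, self.ids):
            if len(arr) != n:
                raise ValueError("panel column lengths differ")
        if np.any(self.ref == self.alt):
            raise ValueError("ref == alt at some site")
        # sortedness: positions and genetic positions within each chromosome
        for c in self.chromosomes:
            m = self.chrom == c
            if np.any(np.diff(self.pos[m]) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")
            if np.any(np.diff(self.gpos[m]) < 0):
                raise ValueError(f"genetic positions decrease on {c}")

    def __len__(self) -> int:
        return len(self.pos)

    @property
    def n_snps(self) -> int:
        return len(self.pos)

    @property
    def chromosomes(self) -> list[str]:
        """Chromosome labels in order of first appearance."""
        seen, out = set(), []
        for c in self.chrom:
            if c not in seen:
                seen.add(c)
                out.append(c)
        return out

    @property
    def strand_ambiguous(self) -> np.ndarray:
        """True where {ref, alt} is {A,T} or {C,G}."""
        comp = np.array([COMPLEMENT.get(b, "?") for b in self.ref])
        return comp == self.alt

    def chrom_mask(self, c: str) -> np.ndarray:
        return self.chrom == c

    def subset(self, mask: np.ndarray) -> "SNPPanel":
        return SNPPanel(
            self.chrom[mask], self.pos[mask], self.gpos[mask],
            self.ref[mask], self.alt[mask], self.ids[mask],
        )

    def site_index(self) -> dict[tuple[str, int], int]:
        """Map (chromosome, position) -> row index."""
        return {
            (c, int(p)): i
            for i, (c, p) in enumerate(zip(self.chrom, self.pos))
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids, "chrom": self.chrom, "gpos": self.gpos,
                "pos": self.pos, "ref": self.ref, "alt": self.alt,
            }
        )

    @classmethod
    def uniform(
        cls,
        n_snps_per_chrom: int,
        n_chrom: int = 1,
        chrom_length_bp: int = 100_000_000,
        cM_per_Mb: float = 1.0,
        alleles: tuple[str, str] = ("A", "G"),
        seed: int | None = None,
    ) -> "SNPPanel":
        """Evenly spaced panel with a linear genetic map (default 1 cM/Mb).

        With ``seed`` given, ref/alt pairs are drawn at random from the
        non-strand-ambiguous transversion/transition pairs; otherwise every
        site carries ``alleles``.
        """
        spacing = chrom_length_bp // (n_snps_per_chrom + 1)
        pos1 = spacing * (1 + np.arange(n_snps_per_chrom))
        chroms, poss = [], []
        for c in range(1, n_chrom + 1):
            chroms.append(np.full(n_snps_per_chrom, str(c)))
            poss.append(pos1)
        chrom = np.concatenate(chroms)
        pos = np.concatenate(poss)
        gpos = pos * (cM_per_Mb / 100.0) / 1e6  # Morgans
        n = len(pos)
        if seed is None:
            ref = np.full(n, alleles[0])
            alt = np.full(n, alleles[1])
        else:
            rng = np.random.default_rng(seed)
            pairs = [("A", "G"), ("G", "A"), ("C", "T"), ("T", "C"),
                     ("A", "C"), ("C", "A"), ("G", "T"), ("T", "G")]
            idx = rng.integers(0, len(pairs), size=n)
            ref = np.array([pairs[i][0] for i in idx])
            alt = np.array([pairs[i][1] for i in idx])
        return cls(chrom, pos, gpos, ref, alt)
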