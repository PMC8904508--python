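"""Genotype containers shared across modules.

Values are alternative-allele counts: ``{0, 1}`` for pseudo-haploid calls
(ploidy 1), ``{0, 1, 2}`` for diploid genotypes (ploidy 2), and
``MISSING = -1`` for no data. Rows are individuals, columns are the SNPs of
an attached :class:`~adnakit.panel.SNPPanel`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .panel import SNPPanel

__all__ = ["GenotypeMatrix", "MISSING"]

MISSING = -1


@dataclass
class GenotypeMatrix:
    """Individuals-by-SNPs genotype matrix of alt-allele counts."""

    panel: SNPPanel
    individuals: list[str]
    values: np.ndarray  # (n_ind, n_snp) int8, MISSING = -1
    ploidy: int = 2
    groups: dict[str, str] = field(default_factory=dict)  # individual -> pop

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.int8)
        self.individuals = [str(i) for i in self.individuals]
        if self.values.shape != (len(self.individuals), len(self.panel)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.panel)} SNPs"
            )
        bad = (self.values != MISSING) & (
            (self.values < 0) | (self.values > self.ploidy)
        )
        if np.any(bad):
            raise ValueError("genotype values outside {0..ploidy, MISSING}")
        if self.ploidy not in (1, 2):
            raise ValueError("ploidy must be 1 or 2")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def missing_mask(self) -> np.ndarray:
        return self.values == MISSING

    def row(self, individual: str) -> np.ndarray:
        return self.values[self.individuals.index(individual)]

    def group_of(self, individual: str) -> str:
        return self.groups.get(individual, individual)

    def subset_individuals(self, keep: list[str]) -> "GenotypeMatrix":
        idx = [self.individuals.index(i) for i in keep]
        return GenotypeMatrix(
            self.panel, list(keep), self.values[idx], self.ploidy,
            {i: self.groups[i] for i in keep if i in self.groups},
        )

    def subset_sites(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.panel.subset(mask), list(self.individuals),
            self.values[:, mask], self.ploidy, dict(self.groups),
        )
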