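"""Shared in-memory containers.

Tabular data (SNP maps, gene annotation, summary statistics, phenotypes,
scores) travels as :class:`pandas.DataFrame` with documented column names;
the two non-tabular containers live here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["MISSING", "GenotypeMatrix", "GeneSet", "GeneSetCollection"]

#: sentinel for a missing genotype call in a :class:`GenotypeMatrix`
MISSING = -1


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs matrix of allele counts.

    ``calls`` is int8 with entries in {0, 1, 2, MISSING}; column ``j``
    corresponds to row ``j`` of ``snp_map`` (columns ``snp_id``,
    ``chromosome``, ``position``).
    """

    calls: np.ndarray
    snp_map: pd.DataFrame

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValueError("calls must be 2-D (individuals x SNPs)")
        if self.calls.shape[1] != len(self.snp_map):
            raise ValueError("number of genotype columns must match the SNP map")

    @property
    def n_individuals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_snps(self) -> int:
        return self.calls.shape[1]

    @property
    def snp_ids(self) -> np.ndarray:
        return self.snp_map["snp_id"].to_numpy()

    def subset_snps(self, snp_ids) -> "GenotypeMatrix":
        """Columns restricted to ``snp_ids`` (original column order kept)."""
        wanted = set(snp_ids)
        mask = self.snp_map["snp_id"].isin(wanted).to_numpy()
        return GenotypeMatrix(self.calls[:, mask], self.snp_map.loc[mask].reset_index(drop=True))


@dataclass(frozen=True)
class GeneSet:
    """A named, ordered gene set (order is rank order where meaningful)."""

    name: str
    genes: tuple[str, ...]
    description: str = ""
    capped: bool = False

    def __post_init__(self) -> None:
        genes = tuple(self.genes)
        if len(set(genes)) != len(genes):
            raise ValueError(f"gene set {self.name!r} contains duplicate genes")
        if not genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        object.__setattr__(self, "genes", genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes


@dataclass
class GeneSetCollection:
    """Ordered collection of uniquely named gene sets (GMT-shaped)."""

    sets: list[GeneSet] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(set(names)) != len(names):
            raise ValueError("duplicate gene set names in collection")

    def add(self, gene_set: GeneSet) -> None:
        if any(s.name == gene_set.name for s in self.sets):
            raise ValueError(f"duplicate gene set name {gene_set.name!r}")
        self.sets.append(gene_set)

    def extend(self, other: "GeneSetCollection") -> None:
        for s in other.sets:
            self.add(s)

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sets]
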