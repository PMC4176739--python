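"""Phased haplotype panel: the in-memory substrate of every pipeline stage.

A :class:`HaplotypePanel` holds biallelic, fully phased haplotypes for a set
of animals together with a sorted SNP map.  Alleles are coded 0 (allele A)
and 1 (allele B); -1 marks a missing call.  Haplotype rows come in adjacent
pairs per animal: row ``2*i`` is the paternal and row ``2*i + 1`` the
maternal chromosome copy of animal ``i``.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MISSING = -1

#: bp per Morgan used when emitting physical coordinates (uniform 1 cM/Mb map).
BP_PER_MORGAN = 100_000_000


@dataclass
class HaplotypePanel:
    snp_map: pd.DataFrame
    haplotypes: np.ndarray
    animal_ids: np.ndarray
    group: str | None = None

    def __post_init__(self) -> None:
        self.animal_ids = np.asarray(self.animal_ids, dtype=object)
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotypes must be a 2-D (haplotype x SNP) array")
        if self.haplotypes.shape[0] != 2 * len(self.animal_ids):
            raise ValueError(
                f"{self.haplotypes.shape[0]} haplotype rows for "
                f"{len(self.animal_ids)} animals; expected exactly two per animal"
            )
        required = {"chrom", "pos", "id"}
        if not required.issubset(self.snp_map.columns):
            raise ValueError(f"snp_map needs columns {sorted(required)}")
        if self.haplotypes.shape[1] != len(self.snp_map):
            raise ValueError("haplotype columns do not match the SNP map")
        self._check_map_sorted()

    def _check_map_sorted(self) -> None:
        chrom = self.snp_map["chrom"].to_numpy()
        pos = self.snp_map["pos"].to_numpy()
        order = np.lexsort((pos, chrom))
        if not np.array_equal(order, np.arange(len(pos))):
            raise ValueError("SNP map must be sorted by (chromosome, position)")
        same = chrom[1:] == chrom[:-1]
        if np.any(pos[1:][same] <= pos[:-1][same]):
            raise ValueError("positions must be strictly increasing within a chromosome")

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    @property
    def n_snps(self) -> int:
        return self.haplotypes.shape[1]

    def dosage(self) -> np.ndarray:
        """Per-animal B-allele count (0/1/2); NaN where either allele is missing."""
        h = self.haplotypes.astype(float)
        h[self.haplotypes == MISSING] = np.nan
        return h[0::2] + h[1::2]

    def allele_frequency(self) -> np.ndarray:
        """Sample B-allele frequency per SNP over non-missing haplotypes."""
        h = self.haplotypes
        called = h != MISSING
        with np.errstate(invalid="ignore"):
            return np.where(called, h, 0).sum(axis=0) / called.sum(axis=0)

    def chromosome_blocks(self) -> list[tuple[int, slice]]:
        """Contiguous column slice per chromosome, in map order."""
        chrom = self.snp_map["chrom"].to_numpy()
        blocks: list[tuple[int, slice]] = []
        start = 0
        for i in range(1, len(chrom) + 1):
            if i == len(chrom) or chrom[i] != chrom[start]:
                blocks.append((int(chrom[start]), slice(start, i)))
                start = i
        return blocks

    def subset_animals(self, index: np.ndarray, group: str | None = None) -> "HaplotypePanel":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        hap_rows = np.stack([2 * index, 2 * index + 1], axis=1).ravel()
        return HaplotypePanel(
            snp_map=self.snp_map,
            haplotypes=self.haplotypes[hap_rows],
            animal_ids=self.animal_ids[index],
            group=group if group is not None else self.group,
        )

    def subset_snps(self, index: np.ndarray) -> "HaplotypePanel":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return HaplotypePanel(
            snp_map=self.snp_map.iloc[index].reset_index(drop=True),
            haplotypes=self.haplotypes[:, index],
            animal_ids=self.animal_ids,
            group=self.group,
        )


def concat_panels(panels: list[HaplotypePanel]) -> HaplotypePanel:
    """Stack animals from panels sharing an identical SNP map."""
    first = panels[0]
    for p in panels[1:]:
        if not first.snp_map[["chrom", "pos"]].equals(p.snp_map[["chrom", "pos"]]):
            raise ValueError("panels must share the same SNP map")
    return HaplotypePanel(
        snp_map=first.snp_map,
        haplotypes=np.vstack([p.haplotypes for p in panels]),
        animal_ids=np.concatenate([p.animal_ids for p in panels]),
        group=None,
    )


def uniform_snp_map(
    n_chromosomes: int, snps_per_chromosome: int, chromosome_length: float
) -> pd.DataFrame:
    """Evenly spaced SNP map; genetic position in Morgans, physical in bp.

    Uses a uniform 1 cM/Mb equivalence (``BP_PER_MORGAN`` bp per Morgan).
    """
    rows = []
    for c in range(1, n_chromosomes + 1):
        gen = (np.arange(snps_per_chromosome) + 0.5) * (
            chromosome_length / snps_per_chromosome
        )
        bp = np.round(gen * BP_PER_MORGAN).astype(np.int64)
        for j, (g, b) in enumerate(zip(gen, bp)):
            rows.append((c, int(b), f"snp_{c}_{j:06d}", float(g)))
    return pd.DataFrame(rows, columns=["chrom", "pos", "id", "gen_pos"])
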