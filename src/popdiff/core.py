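"""Core containers shared by every analysis stage.

All coordinates are 1-based inclusive (NCBI Build 37 convention). Genotypes
count copies of ``allele1``; missing genotypes are encoded as -1. Haplotype
panels are strictly binary with no missing entries: rows ``2i`` and ``2i+1``
are the two phased chromosomes of sample ``i``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MISSING = -1

_SNPMAP_COLUMNS = ("snp_id", "chrom", "pos", "allele0", "allele1")


@dataclass(frozen=True)
class SnpMap:
    """Ordered marker metadata: id, chromosome, position and allele pair.

    Positions must be strictly increasing within each chromosome and snp_ids
    unique; the two alleles of a marker must differ.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        missing_cols = set(_SNPMAP_COLUMNS) - set(t.columns)
        if missing_cols:
            raise ValueError(f"SnpMap table missing columns: {sorted(missing_cols)}")
        t = t.loc[:, list(_SNPMAP_COLUMNS)].reset_index(drop=True)
        t["pos"] = t["pos"].astype(np.int64)
        t["chrom"] = t["chrom"].astype(str)
        if t["snp_id"].duplicated().any():
            dup = t.loc[t["snp_id"].duplicated(), "snp_id"].iloc[0]
            raise ValueError(f"duplicate snp_id: {dup!r}")
        for chrom, grp in t.groupby("chrom", sort=False):
            if not np.all(np.diff(grp["pos"].to_numpy()) > 0):
                raise ValueError(f"positions not strictly increasing on chrom {chrom!r}")
        if (t["allele0"] == t["allele1"]).any():
            bad = t.loc[t["allele0"] == t["allele1"], "snp_id"].iloc[0]
            raise ValueError(f"allele0 == allele1 for {bad!r}")
        object.__setattr__(self, "table", t)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def snp_ids(self) -> np.ndarray:
        return self.table["snp_id"].to_numpy()

    @property
    def positions(self) -> np.ndarray:
        return self.table["pos"].to_numpy()

    @property
    def chroms(self) -> np.ndarray:
        return self.table["chrom"].to_numpy()

    def subset(self, index: np.ndarray) -> "SnpMap":
        """Positional subset (boolean mask or integer indices, order preserved)."""
        sub = self.table.iloc[np.asarray(index)].reset_index(drop=True)
        return SnpMap(sub)

    def window_mask(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Boolean mask of markers with ``start <= pos <= end`` on ``chrom``."""
        t = self.table
        return ((t["chrom"] == str(chrom)) & (t["pos"] >= start) & (t["pos"] <= end)).to_numpy()

    def equals(self, other: "SnpMap") -> bool:
        return self.table.equals(other.table)


@dataclass(frozen=True)
class GeneRegion:
    """A named genomic interval, 1-based and inclusive on both ends."""

    name: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"region {self.name!r}: start {self.start} > end {self.end}")
        if self.start < 1:
            raise ValueError(f"region {self.name!r}: start must be >= 1")


def _check_samples(values: np.ndarray, sample_ids: Sequence[str],
                   populations: Sequence[str], rows_per_sample: int) -> None:
    if len(sample_ids) != len(populations):
        raise ValueError("sample_ids and populations lengths differ")
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("duplicate sample ids")
    if values.shape[0] != rows_per_sample * len(sample_ids):
        raise ValueError(
            f"matrix has {values.shape[0]} rows for {len(sample_ids)} samples "
            f"(expected {rows_per_sample} per sample)")


@dataclass
class GenotypeMatrix:
    """Unphased genotype matrix: samples x markers, entries in {0,1,2,-1}."""

    values: np.ndarray
    sample_ids: list[str]
    populations: list[str]
    snp_map: SnpMap

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        self.sample_ids = list(self.sample_ids)
        self.populations = list(self.populations)
        _check_samples(self.values, self.sample_ids, self.populations, 1)
        if self.values.shape[1] != len(self.snp_map):
            raise ValueError("column count does not match SnpMap length")
        valid = np.isin(self.values, (0, 1, 2, MISSING))
        if not valid.all():
            raise ValueError("genotype entries must be 0, 1, 2 or missing (-1)")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    def population_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(p, None)
        return list(seen)

    def subset_markers(self, index: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(index)
        return GenotypeMatrix(self.values[:, idx] if idx.dtype != bool else self.values[:, idx],
                              self.sample_ids, self.populations, self.snp_map.subset(idx))

    def subset_samples(self, index: Iterable[int]) -> "GenotypeMatrix":
        idx = np.asarray(list(index), dtype=int)
        return GenotypeMatrix(self.values[idx], [self.sample_ids[i] for i in idx],
                              [self.populations[i] for i in idx], self.snp_map)

    def by_population(self) -> dict[str, "GenotypeMatrix"]:
        pops = np.asarray(self.populations)
        return {p: self.subset_samples(np.flatnonzero(pops == p))
                for p in self.population_names()}

    def allele_frequencies(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-marker allele-1 frequency and call count, missing excluded."""
        called = self.values != MISSING
        n_called = called.sum(axis=0)
        alt = np.where(called, self.values, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(n_called > 0, alt / (2.0 * n_called), np.nan)
        return freq, n_called


@dataclass
class HaplotypePanel:
    """Phased binary haplotypes: (2 x samples) x markers, no missing data."""

    values: np.ndarray
    sample_ids: list[str]
    populations: list[str]
    snp_map: SnpMap

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.uint8)
        self.sample_ids = list(self.sample_ids)
        self.populations = list(self.populations)
        _check_samples(self.values, self.sample_ids, self.populations, 2)
        if self.values.shape[1] != len(self.snp_map):
            raise ValueError("column count does not match SnpMap length")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("haplotype entries must be 0 or 1")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_haplotypes(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    @property
    def haplotype_populations(self) -> list[str]:
        """Population label of every haplotype row (each sample's twice)."""
        return [p for p in self.populations for _ in (0, 1)]

    def population_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(p, None)
        return list(seen)

    def to_genotypes(self) -> GenotypeMatrix:
        g = self.values[0::2].astype(np.int8) + self.values[1::2].astype(np.int8)
        return GenotypeMatrix(g, self.sample_ids, self.populations, self.snp_map)

    def subset_markers(self, index: np.ndarray) -> "HaplotypePanel":
        idx = np.asarray(index)
        return HaplotypePanel(self.values[:, idx], self.sample_ids,
                              self.populations, self.snp_map.subset(idx))

    def subset_samples(self, index: Iterable[int]) -> "HaplotypePanel":
        idx = np.asarray(list(index), dtype=int)
        rows = np.empty(2 * len(idx), dtype=int)
        rows[0::2] = 2 * idx
        rows[1::2] = 2 * idx + 1
        return HaplotypePanel(self.values[rows], [self.sample_ids[i] for i in idx],
                              [self.populations[i] for i in idx], self.snp_map)

    def by_population(self) -> dict[str, "HaplotypePanel"]:
        pops = np.asarray(self.populations)
        return {p: self.subset_samples(np.flatnonzero(pops == p))
                for p in self.population_names()}

    def allele_frequencies(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-marker allele-1 frequency over all haplotype rows, and counts."""
        n = np.full(self.n_markers, self.n_haplotypes)
        return self.values.mean(axis=0), n

    @staticmethod
    def concat(panels: Sequence["HaplotypePanel"]) -> "HaplotypePanel":
        """Stack panels sample-wise; all must share an identical SnpMap."""
        if not panels:
            raise ValueError("no panels to concatenate")
        first = panels[0]
        for p in panels[1:]:
            if not p.snp_map.equals(first.snp_map):
                raise ValueError("panels have different marker maps")
        return HaplotypePanel(
            np.vstack([p.values for p in panels]),
            [s for p in panels for s in p.sample_ids],
            [l for p in panels for l in p.populations],
            first.snp_map,
        )
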