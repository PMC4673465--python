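"""Gene-region haplotype catalogs, major haplotypes, dissimilarity and
ancestry-group sharing.

A catalog enumerates the distinct SNP haplotypes observed in a gene region
(gene coordinates plus a 100 kb buffer on each side) and their frequency in
every population. "Major" haplotypes are those reaching a frequency
threshold in at least one population (10% for HLA-A/-B/-C/-DR, 6% for
HLA-DQ/-DP by convention). Dissimilarity between two haplotypes is the
percentage of SNP sites at which they carry different alleles.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import GeneRegion, HaplotypePanel, SnpMap

DEFAULT_BUFFER_BP = 100_000


def extend_region(region: GeneRegion, buffer: int = DEFAULT_BUFFER_BP) -> GeneRegion:
    """Append a buffer up- and downstream; the start is clamped at 1."""
    if buffer < 0:
        raise ValueError("buffer must be non-negative")
    return GeneRegion(region.name, region.chrom,
                      max(1, region.start - buffer), region.end + buffer)


@dataclass
class HaplotypeCatalog:
    """Distinct haplotypes of one region with per-population counts."""

    region: GeneRegion
    snp_map: SnpMap                 # the region's marker subset
    haplotypes: list[str]           # binary strings, first-appearance order
    counts: pd.DataFrame            # populations x haplotypes, int
    frequencies: pd.DataFrame       # populations x haplotypes, rows sum to 1

    def __post_init__(self) -> None:
        sums = self.frequencies.sum(axis=1).to_numpy()
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("each population's haplotype frequencies must sum to 1")

    @property
    def n_markers(self) -> int:
        return len(self.snp_map)

    @property
    def populations(self) -> list[str]:
        return list(self.frequencies.index)


def extract_region_haplotypes(panel: HaplotypePanel,
                              region: GeneRegion) -> HaplotypeCatalog:
    """Catalog the distinct haplotypes a panel carries inside a region.

    Markers with ``start <= pos <= end`` (inclusive) are used; frequencies
    are haplotype counts over 2 x (population sample count). Raises when the
    region contains no markers.
    """
    mask = panel.snp_map.window_mask(region.chrom, region.start, region.end)
    if not mask.any():
        raise ValueError(f"region {region.name!r} contains no markers")
    sub = panel.subset_markers(mask)
    rows = sub.values
    # distinct haplotypes in order of first appearance
    _, first_idx, inverse = np.unique(rows, axis=0, return_index=True,
                                      return_inverse=True)
    order = np.argsort(first_idx, kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    hap_of_row = rank[inverse]
    haplotypes = ["".join(map(str, rows[first_idx[k]])) for k in order]
    pops = np.asarray(sub.haplotype_populations)
    pop_names = sub.population_names()
    counts = np.zeros((len(pop_names), len(haplotypes)), dtype=int)
    for i, pop in enumerate(pop_names):
        sel = hap_of_row[pops == pop]
        np.add.at(counts[i], sel, 1)
    counts_df = pd.DataFrame(counts, index=pop_names, columns=haplotypes)
    freqs = counts_df.div(counts_df.sum(axis=1), axis=0)
    return HaplotypeCatalog(region, sub.snp_map, haplotypes, counts_df, freqs)


@dataclass
class MajorHaplotypeSet:
    """Haplotypes reaching the frequency threshold in >= 1 population,
    labelled H1..Hn by descending maximum population frequency."""

    catalog: HaplotypeCatalog
    threshold: float
    labels: list[str]
    haplotypes: list[str]  # aligned with labels

    @property
    def frequencies(self) -> pd.DataFrame:
        """Populations x major haplotypes, columns relabelled H1..Hn."""
        f = self.catalog.frequencies.loc[:, self.haplotypes].copy()
        f.columns = self.labels
        return f

    def __len__(self) -> int:
        return len(self.labels)


def major_haplotypes(catalog: HaplotypeCatalog, threshold: float) -> MajorHaplotypeSet:
    """Select haplotypes whose maximum per-population frequency is >= threshold
    (inclusive), ordered by descending maximum frequency, ties by string."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    maxfreq = catalog.frequencies.max(axis=0)
    members = [(h, maxfreq[h]) for h in catalog.haplotypes if maxfreq[h] >= threshold]
    members.sort(key=lambda hv: (-hv[1], hv[0]))
    haps = [h for h, _ in members]
    labels = [f"H{i + 1}" for i in range(len(haps))]
    return MajorHaplotypeSet(catalog, threshold, labels, haps)


def dissimilarity(h1: str, h2: str) -> float:
    """Percentage of SNP sites at which two haplotypes differ."""
    if len(h1) != len(h2):
        raise ValueError("haplotypes have different lengths")
    if len(h1) == 0:
        raise ValueError("haplotypes must be non-empty")
    diff = sum(a != b for a, b in zip(h1, h2))
    return 100.0 * diff / len(h1)


def dissimilarity_matrix(major: MajorHaplotypeSet) -> pd.DataFrame:
    """Full pairwise dissimilarity between the major haplotypes (percent)."""
    n = len(major)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = dissimilarity(major.haplotypes[i],
                                              major.haplotypes[j])
    return pd.DataFrame(m, index=major.labels, columns=major.labels)


def min_dissimilarity_table(major: MajorHaplotypeSet) -> pd.Series:
    """Per major haplotype, the dissimilarity to its nearest other major
    haplotype. A single-member set yields NaN (written as the dash marker)."""
    n = len(major)
    if n == 0:
        raise ValueError("no major haplotypes")
    if n == 1:
        return pd.Series([np.nan], index=major.labels)
    full = dissimilarity_matrix(major)
    vals = full.to_numpy().copy()
    np.fill_diagonal(vals, np.inf)
    return pd.Series(vals.min(axis=1), index=major.labels)


def format_dissimilarity(values: pd.Series | pd.DataFrame):
    """Two-decimal percentage strings, NaN rendered as the en-dash marker."""
    def fmt(x):
        return "–" if pd.isna(x) else f"{x:.2f}"
    return values.map(fmt) if isinstance(values, pd.Series) else values.applymap(fmt)


def sharing_classification(major: MajorHaplotypeSet,
                           groups: Mapping[str, str]) -> dict[str, frozenset[str]]:
    """Assign each major haplotype to the set of ancestry groups where it has
    non-zero frequency in at least one member population."""
    unassigned = [p for p in major.catalog.populations if p not in groups]
    if unassigned:
        raise ValueError(f"populations not assigned to any group: {unassigned}")
    freqs = major.catalog.frequencies
    out: dict[str, frozenset[str]] = {}
    for label, hap in zip(major.labels, major.haplotypes):
        present = {groups[p] for p in major.catalog.populations
                   if freqs.loc[p, hap] > 0}
        out[label] = frozenset(present)
    return out


def venn_counts(classification: Mapping[str, frozenset[str]]) -> Counter:
    """Counts of major haplotypes per Venn cell (subset of ancestry groups)."""
    return Counter(classification.values())
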