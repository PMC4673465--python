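"""F_ST estimators and the pooled top-quantile enrichment test.

SNP-level F_ST between two populations follows the Nei form

    F_ST = (p1 - p2)^2 / (4 p_bar (1 - p_bar)),   p_bar = (p1 + p2) / 2,

which is (H_T - H_S) / H_T for two equally weighted populations at a
biallelic site. The multi-allelic (haplotype-level) generalisation G_ST uses
expected heterozygosities over the haplotype frequency spectrum. A
Weir–Cockerham sample-size-corrected SNP estimator is available as a
sensitivity switch.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom

from .core import GenotypeMatrix, HaplotypePanel, SnpMap

# default marker window: the 10 Mb MHC-bearing interval on chromosome 6
MHC_WINDOW = ("6", 25_000_000, 35_000_000)


@dataclass
class FstMatrix:
    """Symmetric K x K distance matrix of pairwise F_ST values."""

    values: np.ndarray
    populations: list[str]
    n_markers: np.ndarray  # per-cell marker count actually averaged

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape[0] != v.shape[1] or v.shape[0] != len(self.populations):
            raise ValueError("matrix shape does not match population list")
        if not np.allclose(v, v.T):
            raise ValueError("F_ST matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("F_ST matrix diagonal must be zero")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("F_ST entries must lie in [0, 1]")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.populations,
                            columns=self.populations)


def _validate_freqs(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("allele frequencies must lie in [0, 1]")
    return p


def snp_fst(p1, p2):
    """Nei two-population F_ST from the allele frequencies at one SNP.

    Accepts scalars or arrays (broadcast elementwise). Monomorphic sites
    (pooled frequency 0 or 1) return 0.
    """
    p1 = _validate_freqs(p1)
    p2 = _validate_freqs(p2)
    pbar = (p1 + p2) / 2.0
    denom = 4.0 * pbar * (1.0 - pbar)
    num = (p1 - p2) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
    if np.ndim(out) == 0:
        return float(out)
    return out


def snp_fst_weir_cockerham(p1, p2, n1, n2):
    """Weir–Cockerham theta for two populations of n1 and n2 haplotypes.

    Sample-size-corrected alternative to :func:`snp_fst`. Individual
    estimates may be slightly negative under no differentiation; they are
    left uncorrected so that averages over markers stay unbiased (clipping
    happens at the matrix level).
    """
    p1, p2 = _validate_freqs(p1), _validate_freqs(p2)
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    r = 2.0
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r)
        tot = a + b
        out = np.where(tot != 0, a / np.where(tot != 0, tot, 1.0), 0.0)
    out = np.minimum(out, 1.0)
    return float(out) if np.ndim(out) == 0 else out


def _pop_freqs(data_by_pop: Mapping[str, GenotypeMatrix | HaplotypePanel]):
    pops = list(data_by_pop)
    first = data_by_pop[pops[0]].snp_map
    freqs, counts = {}, {}
    for pop, d in data_by_pop.items():
        if not d.snp_map.equals(first):
            raise ValueError("all populations must share a common SnpMap")
        f, n = d.allele_frequencies()
        freqs[pop], counts[pop] = f, n
    return pops, first, freqs, counts


def default_marker_mask(snp_map: SnpMap) -> np.ndarray:
    """Markers in the chr6 25–35 Mb window if any are present, else all."""
    mask = snp_map.window_mask(*MHC_WINDOW)
    return mask if mask.any() else np.ones(len(snp_map), dtype=bool)


def mean_fst_matrix(data_by_pop: Mapping[str, GenotypeMatrix | HaplotypePanel],
                    markers: np.ndarray | None = None,
                    estimator: str = "nei") -> FstMatrix:
    """Pairwise population distance matrix: mean SNP F_ST over a marker set.

    ``markers`` is a boolean mask over the shared SnpMap; by default the
    chr6 25–35 Mb window (all markers when the map lies elsewhere). Markers
    with zero calls in either population of a pair are skipped for that pair.
    """
    if len(data_by_pop) < 2:
        raise ValueError("need at least two populations")
    if estimator not in ("nei", "weir_cockerham"):
        raise ValueError(f"unknown estimator {estimator!r}")
    pops, snp_map, freqs, counts = _pop_freqs(data_by_pop)
    mask = default_marker_mask(snp_map) if markers is None else np.asarray(markers)
    if mask.dtype != bool:
        full = np.zeros(len(snp_map), dtype=bool)
        full[mask] = True
        mask = full
    K = len(pops)
    vals = np.zeros((K, K))
    nmat = np.zeros((K, K), dtype=int)
    for i in range(K):
        for j in range(i + 1, K):
            fi, fj = freqs[pops[i]], freqs[pops[j]]
            ni, nj = counts[pops[i]], counts[pops[j]]
            ok = mask & (ni > 0) & (nj > 0)
            n_skipped = int(mask.sum() - ok.sum())
            if n_skipped:
                warnings.warn(f"{n_skipped} markers with no calls skipped for "
                              f"pair ({pops[i]}, {pops[j]})")
            if not ok.any():
                raise ValueError(f"no usable markers for pair ({pops[i]}, {pops[j]})")
            if estimator == "nei":
                cell = snp_fst(fi[ok], fj[ok]).mean()
            else:
                cell = max(0.0, snp_fst_weir_cockerham(fi[ok], fj[ok],
                                                       ni[ok], nj[ok]).mean())
            vals[i, j] = vals[j, i] = cell
            nmat[i, j] = nmat[j, i] = int(ok.sum())
    return FstMatrix(vals, pops, nmat)


def haplotype_gst(freqs1, freqs2) -> float:
    """Multi-allelic F_ST (G_ST) from two haplotype frequency vectors.

    G_ST = (H_T - H_S) / H_T with H_S the mean within-population expected
    heterozygosity and H_T the heterozygosity of the pooled (mean) frequency
    vector. Returns 0 when H_T = 0 (one shared haplotype everywhere).
    """
    f1 = np.asarray(freqs1, dtype=float)
    f2 = np.asarray(freqs2, dtype=float)
    if f1.shape != f2.shape:
        raise ValueError("haplotype frequency vectors have different lengths")
    for f in (f1, f2):
        if abs(f.sum() - 1.0) > 1e-9:
            raise ValueError("haplotype frequencies must sum to 1")
    hs = 1.0 - ((f1 ** 2).sum() + (f2 ** 2).sum()) / 2.0
    pbar = (f1 + f2) / 2.0
    ht = 1.0 - (pbar ** 2).sum()
    if ht <= 0.0:
        return 0.0
    return float((ht - hs) / ht)


def haplotype_fst_matrix(frequencies: pd.DataFrame) -> FstMatrix:
    """K x K haplotype-level F_ST matrix from a populations x haplotypes
    frequency table (one gene region)."""
    pops = list(frequencies.index)
    K = len(pops)
    f = frequencies.to_numpy()
    vals = np.zeros((K, K))
    for i in range(K):
        for j in range(i + 1, K):
            vals[i, j] = vals[j, i] = haplotype_gst(f[i], f[j])
    if np.all(vals == 0.0):
        warnings.warn("haplotype F_ST matrix is identically zero "
                      "(no haplotype differentiation in this region)")
    n = np.full((K, K), frequencies.shape[1], dtype=int)
    np.fill_diagonal(n, 0)
    return FstMatrix(vals, pops, n)


def pooled_fst_records(data_by_pop: Mapping[str, GenotypeMatrix | HaplotypePanel],
                       markers: np.ndarray | None = None) -> pd.DataFrame:
    """Per-(pair, SNP) F_ST records pooled over all C(K,2) population pairs."""
    pops, snp_map, freqs, counts = _pop_freqs(data_by_pop)
    mask = default_marker_mask(snp_map) if markers is None else np.asarray(markers)
    ids = snp_map.snp_ids[mask]
    rows = []
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            ok = (counts[pops[i]] > 0) & (counts[pops[j]] > 0) & mask
            vals = snp_fst(freqs[pops[i]][mask], freqs[pops[j]][mask])
            rows.append(pd.DataFrame({
                "pop_i": pops[i], "pop_j": pops[j], "snp_id": ids,
                "fst": np.where(ok[mask], vals, np.nan)}))
    out = pd.concat(rows, ignore_index=True).dropna(subset=["fst"])
    return out.reset_index(drop=True)


class EnrichmentResult(NamedTuple):
    count_in_top: int
    n_top: int
    null_prob: float
    p_value: float


def top_fst_enrichment(records: pd.DataFrame, focal: str,
                       quantile: float = 0.01) -> EnrichmentResult:
    """Exact binomial test for over-representation of one population among
    the top-quantile pooled F_ST values.

    Under the null that every pair is equally likely to appear in the top
    fraction, a record involves the focal population with probability
    (K-1)/C(K,2) = 2/K. The p-value is the one-sided upper binomial tail
    P(X >= count_in_top).
    """
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must be in (0, 1)")
    pops = sorted(set(records["pop_i"]) | set(records["pop_j"]))
    if focal not in pops:
        raise ValueError(f"focal population {focal!r} not present in records")
    K = len(pops)
    total = len(records)
    n_top = math.ceil(quantile * total)
    # deterministic order: largest fst first, ties by (pair, snp_id)
    ordered = records.sort_values(["fst", "pop_i", "pop_j", "snp_id"],
                                  ascending=[False, True, True, True],
                                  kind="mergesort").head(n_top)
    count = int(((ordered["pop_i"] == focal) | (ordered["pop_j"] == focal)).sum())
    null_prob = 2.0 / K
    p = float(binom.sf(count - 1, n_top, null_prob))
    return EnrichmentResult(count, n_top, null_prob, p)
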