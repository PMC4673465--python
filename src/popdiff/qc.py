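"""Marker-level quality control and cross-panel marker intersection.

QC mirrors standard SNP-array practice: markers are kept when their call rate
is strictly above a threshold (default 95%) and when an exact Hardy–Weinberg
test shows no departure from equilibrium (P > 0.05). HWE is tested within
each population separately by default and a marker must pass in every
population; a pooled mode is available.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy.special import gammaln

from .core import MISSING, GenotypeMatrix, HaplotypePanel, SnpMap

# reverse-complement lookup for strand checks
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def call_rate_filter(g: GenotypeMatrix, min_rate: float) -> GenotypeMatrix:
    """Keep markers whose non-missing fraction is strictly greater than min_rate."""
    if not 0.0 <= min_rate <= 1.0:
        raise ValueError("min_rate must be in [0, 1]")
    called = (g.values != MISSING).mean(axis=0)
    return g.subset_markers(called > min_rate)


def _hwe_het_log_probs(n_het_values: np.ndarray, n_rare: int, n_genotypes: int) -> np.ndarray:
    """Unnormalised log-probabilities of heterozygote counts conditional on
    the allele counts (n_rare copies of the rarer allele among n_genotypes
    diploid individuals)."""
    n_common = 2 * n_genotypes - n_rare
    h = n_het_values
    n_rare_hom = (n_rare - h) // 2
    n_common_hom = (n_common - h) // 2
    return (h * np.log(2.0)
            - gammaln(n_rare_hom + 1) - gammaln(h + 1) - gammaln(n_common_hom + 1))


def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Two-sided exact Hardy–Weinberg p-value from genotype counts.

    Conditional on the observed allele counts, sums the probabilities of all
    heterozygote counts no more probable than the observed one (the standard
    exact test of Wigginton, Cutler & Abecasis 2005).
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n == 0:
        raise ValueError("all genotype counts are zero")
    n_a = 2 * n_aa + n_ab
    n_rare = min(n_a, 2 * n - n_a)
    if n_rare == 0:  # monomorphic: a single outcome
        return 1.0
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    logp = _hwe_het_log_probs(hets, n_rare, n)
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    obs = probs[np.searchsorted(hets, n_ab)]
    return float(min(1.0, probs[probs <= obs * (1 + 1e-12)].sum()))


def _genotype_counts(col: np.ndarray) -> tuple[int, int, int]:
    called = col[col != MISSING]
    return int((called == 0).sum()), int((called == 1).sum()), int((called == 2).sum())


def hwe_filter(g: GenotypeMatrix, alpha: float = 0.05,
               per_population: bool = True) -> GenotypeMatrix:
    """Keep markers with exact-HWE p-value > alpha.

    With ``per_population=True`` (default) the test runs within each
    population and a marker must pass everywhere; otherwise genotype counts
    are pooled across samples. Markers with no calls in a population carry no
    evidence and pass there.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    groups: Sequence[np.ndarray]
    if per_population:
        pops = np.asarray(g.populations)
        groups = [np.flatnonzero(pops == p) for p in g.population_names()]
    else:
        groups = [np.arange(g.n_samples)]
    keep = np.ones(g.n_markers, dtype=bool)
    for j in range(g.n_markers):
        for idx in groups:
            c = _genotype_counts(g.values[idx, j])
            if sum(c) == 0:
                continue
            if hwe_exact_test(*c) <= alpha:
                keep[j] = False
                break
    return g.subset_markers(keep)


def _is_strand_ambiguous(a0: str, a1: str) -> bool:
    return _COMPLEMENT.get(a0.upper()) == a1.upper()


def _alleles_match(a0: str, a1: str, b0: str, b1: str) -> str | None:
    """How dataset B's alleles relate to dataset A's at one site.

    Returns "same" (same orientation), "swap" (allele labels swapped, coding
    must be flipped) or None (irreconcilable). Strand flips are accepted when
    unambiguous (complement of the pair matches).
    """
    a0, a1, b0, b1 = (x.upper() for x in (a0, a1, b0, b1))
    if (b0, b1) == (a0, a1):
        return "same"
    if (b0, b1) == (a1, a0):
        return "swap"
    c0, c1 = _COMPLEMENT.get(b0), _COMPLEMENT.get(b1)
    if (c0, c1) == (a0, a1):
        return "same"
    if (c0, c1) == (a1, a0):
        return "swap"
    return None


def intersect_markers(datasets: Sequence[GenotypeMatrix | HaplotypePanel],
                      drop_ambiguous: bool = True):
    """Restrict all datasets to the markers they share.

    Markers are keyed by (chrom, pos); allele pairs must agree up to allele
    order and strand flip. A/T and C/G markers are dropped by default because
    their strand cannot be resolved across genotyping arrays. When a dataset
    carries the alleles in the opposite order its coding is flipped so all
    outputs share one orientation (the first dataset's). Raises when the
    intersection is empty.
    """
    if len(datasets) < 2:
        raise ValueError("need at least two datasets to intersect")
    lookups = []
    for d in datasets[1:]:
        t = d.snp_map.table
        lookups.append({(c, p): (j, a0, a1) for j, (c, p, a0, a1) in
                        enumerate(zip(t["chrom"], t["pos"], t["allele0"], t["allele1"]))})
    first = datasets[0].snp_map.table
    kept: list[int] = []                       # marker index in the first dataset
    others: list[list[tuple[int, bool]]] = []  # per other dataset: (index, flip)
    for j, (c, p, a0, a1) in enumerate(zip(first["chrom"], first["pos"],
                                           first["allele0"], first["allele1"])):
        if drop_ambiguous and _is_strand_ambiguous(a0, a1):
            continue
        row: list[tuple[int, bool]] = []
        for lut in lookups:
            hit = lut.get((c, p))
            if hit is None:
                break
            k, b0, b1 = hit
            rel = _alleles_match(a0, a1, b0, b1)
            if rel is None:
                break
            row.append((k, rel == "swap"))
        else:
            kept.append(j)
            others.append(row)
    if not kept:
        raise ValueError("marker intersection is empty")
    out = [datasets[0].subset_markers(np.asarray(kept, dtype=int))]
    common_map = out[0].snp_map
    for d_i, d in enumerate(datasets[1:]):
        idx = np.asarray([others[m][d_i][0] for m in range(len(kept))], dtype=int)
        flip = np.asarray([others[m][d_i][1] for m in range(len(kept))], dtype=bool)
        sub = d.subset_markers(idx)
        vals = sub.values.copy()
        if flip.any():
            if isinstance(d, HaplotypePanel):
                vals[:, flip] = 1 - vals[:, flip]
            else:
                cols = vals[:, flip]
                cols[cols != MISSING] = 2 - cols[cols != MISSING]
                vals[:, flip] = cols
        cls = HaplotypePanel if isinstance(d, HaplotypePanel) else GenotypeMatrix
        out.append(cls(vals, sub.sample_ids, sub.populations, common_map))
    return out
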