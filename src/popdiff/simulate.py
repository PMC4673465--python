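"""Synthetic multi-population phased datasets.

Two generative layers are provided:

* :func:`balding_nichols_freqs` / :func:`balding_nichols_panel` — the
  Balding–Nichols model: each marker's ancestral frequency ``p`` is drawn
  Uniform(0.05, 0.95) and each population's frequency is drawn
  ``Beta(p(1-F)/F, (1-p)(1-F)/F)`` independently, so the differentiation
  parameter ``F`` controls the variance of allele-frequency divergence.
  Haplotypes are then independent Bernoulli draws per site — the right null
  for SNP-level F_ST and structure analyses.

* :func:`founder_mosaic_panel` — a founder-haplotype mosaic: a small pool of
  founder haplotypes is shared by all populations, but each population uses
  them with its own Dirichlet-drawn weights. Sampled haplotypes copy a
  founder left to right, switching founders with a per-marker probability
  and flipping alleles with a small mutation rate. This reproduces the
  situation where populations carry the same major haplotypes at different
  frequencies — the structure that haplotype-level F_ST and major-haplotype
  analyses are designed to detect.

Defaults mirror the study design this package targets: K populations of 200
diploid samples over ~1,600 SNPs in a 10 Mb window of chromosome 6.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import HaplotypePanel, SnpMap

# strand-unambiguous allele pairs only, so simulated panels survive
# cross-array marker intersection unscathed
_ALLELE_PAIRS = (("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"))


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic study.

    ``fst_target`` is the Balding–Nichols F governing allele-frequency
    differentiation between populations; ``switch_rate`` and
    ``mutation_rate`` are per-marker probabilities of the founder mosaic;
    ``founder_weight_concentration`` is the symmetric Dirichlet concentration
    for per-population founder usage (smaller = more skewed = more
    haplotype-frequency contrast between populations).
    """

    n_pops: int = 2
    n_samples_per_pop: int = 200
    n_snps: int = 1607
    region_length: int = 10_000_000
    fst_target: float = 0.01
    n_founders: int = 12
    switch_rate: float = 0.02
    mutation_rate: float = 0.002
    founder_weight_concentration: float = 1.0
    seed: int = 0
    chrom: str = "6"
    region_start: int = 25_000_001

    def __post_init__(self) -> None:
        if self.n_pops < 1 or self.n_samples_per_pop < 1 or self.n_snps < 1:
            raise ValueError("population, sample and marker counts must be positive")
        if not 0.0 <= self.fst_target < 1.0:
            raise ValueError("fst_target must be in [0, 1)")
        if self.n_founders < 2:
            raise ValueError("need at least 2 founders")
        if not 0.0 <= self.switch_rate < 1.0:
            raise ValueError("switch_rate must be in [0, 1)")
        if not 0.0 <= self.mutation_rate <= 0.5:
            raise ValueError("mutation_rate must be in [0, 0.5]")
        if self.founder_weight_concentration <= 0:
            raise ValueError("founder_weight_concentration must be positive")
        if self.n_snps > self.region_length:
            raise ValueError("more markers than positions in the region")

    @property
    def population_names(self) -> list[str]:
        return [f"pop{i + 1}" for i in range(self.n_pops)]


@dataclass
class SyntheticDataset:
    """A generated panel together with its generative ground truth."""

    panel: HaplotypePanel
    true_pop_freqs: pd.DataFrame  # populations x markers allele-1 frequency
    founders: np.ndarray | None   # n_founders x markers, None for BN panels
    config: SyntheticConfig


def _rng(config: SyntheticConfig, stream: int) -> np.random.Generator:
    # deterministic sub-stream per operation, all hanging off the one seed
    return np.random.default_rng([config.seed, stream])


def _snp_map(config: SyntheticConfig, rng: np.random.Generator) -> SnpMap:
    pos = np.sort(rng.choice(config.region_length, size=config.n_snps, replace=False))
    pos = pos + config.region_start
    pair_idx = rng.integers(len(_ALLELE_PAIRS), size=config.n_snps)
    return SnpMap(pd.DataFrame({
        "snp_id": [f"snp{i + 1}" for i in range(config.n_snps)],
        "chrom": config.chrom,
        "pos": pos,
        "allele0": [_ALLELE_PAIRS[k][0] for k in pair_idx],
        "allele1": [_ALLELE_PAIRS[k][1] for k in pair_idx],
    }))


def balding_nichols_freqs(config: SyntheticConfig) -> pd.DataFrame:
    """Population allele-frequency table under the Balding–Nichols model.

    Returns a populations x markers DataFrame. At F = 0 every population
    carries the ancestral frequency exactly (degenerate Beta limit).
    """
    rng = _rng(config, 1)
    p = rng.uniform(0.05, 0.95, size=config.n_snps)
    F = config.fst_target
    if F == 0.0:
        freqs = np.tile(p, (config.n_pops, 1))
    else:
        a = p * (1 - F) / F
        b = (1 - p) * (1 - F) / F
        freqs = rng.beta(a, b, size=(config.n_pops, config.n_snps))
    cols = [f"snp{i + 1}" for i in range(config.n_snps)]
    return pd.DataFrame(freqs, index=config.population_names, columns=cols)


def balding_nichols_panel(config: SyntheticConfig) -> SyntheticDataset:
    """Phased panel with independent sites drawn from Balding–Nichols
    population frequencies (no haplotype structure)."""
    freqs = balding_nichols_freqs(config)
    rng = _rng(config, 2)
    snp_map = _snp_map(config, _rng(config, 0))
    n_hap = 2 * config.n_samples_per_pop
    blocks, sample_ids, populations = [], [], []
    for k, pop in enumerate(config.population_names):
        f = freqs.to_numpy()[k]
        blocks.append((rng.random((n_hap, config.n_snps)) < f).astype(np.uint8))
        sample_ids += [f"{pop}_s{i + 1}" for i in range(config.n_samples_per_pop)]
        populations += [pop] * config.n_samples_per_pop
    panel = HaplotypePanel(np.vstack(blocks), sample_ids, populations, snp_map)
    freqs.columns = snp_map.snp_ids
    return SyntheticDataset(panel, freqs, None, config)


def founder_mosaic_panel(config: SyntheticConfig) -> SyntheticDataset:
    """Phased panel of founder-haplotype mosaics with population-specific
    founder weights (shared major haplotypes, differing frequencies)."""
    rng = _rng(config, 3)
    snp_map = _snp_map(config, _rng(config, 0))
    M, K = config.n_snps, config.n_pops
    # founder alleles from one ancestral Balding-Nichols population
    p = rng.uniform(0.05, 0.95, size=M)
    F = config.fst_target
    if F > 0:
        q = rng.beta(p * (1 - F) / F, (1 - p) * (1 - F) / F)
    else:
        q = p
    founders = (rng.random((config.n_founders, M)) < q).astype(np.uint8)
    weights = rng.dirichlet([config.founder_weight_concentration] * config.n_founders,
                            size=K)
    mu = config.mutation_rate
    n_hap = 2 * config.n_samples_per_pop
    blocks, sample_ids, populations, true_freqs = [], [], [], []
    for k, pop in enumerate(config.population_names):
        switch = rng.random((n_hap, M)) < config.switch_rate
        switch[:, 0] = True
        picks = rng.choice(config.n_founders, size=(n_hap, M), p=weights[k])
        # index of the most recent switch point, per row
        last = np.maximum.accumulate(np.where(switch, np.arange(M), 0), axis=1)
        active = picks[np.arange(n_hap)[:, None], last]
        haps = founders[active, np.arange(M)]
        flips = rng.random((n_hap, M)) < mu
        haps = haps ^ flips
        blocks.append(haps.astype(np.uint8))
        sample_ids += [f"{pop}_s{i + 1}" for i in range(config.n_samples_per_pop)]
        populations += [pop] * config.n_samples_per_pop
        base = weights[k] @ founders  # marginal copy probability of allele 1
        true_freqs.append(base * (1 - mu) + (1 - base) * mu)
    panel = HaplotypePanel(np.vstack(blocks), sample_ids, populations, snp_map)
    freq_df = pd.DataFrame(np.vstack(true_freqs), index=config.population_names,
                           columns=snp_map.snp_ids)
    return SyntheticDataset(panel, freq_df, founders, config)


def split_reference_target(panel: HaplotypePanel, n_target_per_pop: int,
                           seed: int) -> tuple[HaplotypePanel, HaplotypePanel]:
    """Split every population into disjoint reference and target sample sets.

    The target gets exactly ``n_target_per_pop`` samples per population
    (e.g. 19 held-out subjects against a 200-sample reference panel).
    """
    if n_target_per_pop < 0:
        raise ValueError("n_target_per_pop must be non-negative")
    rng = np.random.default_rng(seed)
    pops = np.asarray(panel.populations)
    target_idx: list[int] = []
    for pop in panel.population_names():
        members = np.flatnonzero(pops == pop)
        if len(members) <= n_target_per_pop:
            raise ValueError(
                f"population {pop!r} has {len(members)} samples; "
                f"cannot hold out {n_target_per_pop}")
        target_idx += sorted(rng.choice(members, size=n_target_per_pop,
                                        replace=False).tolist())
    target_set = set(target_idx)
    ref_idx = [i for i in range(panel.n_samples) if i not in target_set]
    return panel.subset_samples(ref_idx), panel.subset_samples(sorted(target_idx))
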