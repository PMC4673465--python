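"""Li–Stephens haplotype-copying imputation and the masked-SNP accuracy
protocol.

Each target haplotype is modelled as an imperfect mosaic of the reference
haplotypes: a hidden Markov chain over reference rows that stays on the
current row with probability 1 - rho per marker interval and otherwise jumps
to a uniformly chosen row, emitting the copied allele with miscopy
probability epsilon at typed sites. Masked sites emit nothing; their
posterior allele-1 probability (dosage) comes from the forward–backward
state posterior.

Accuracy follows the masking protocol: hide a random subset of markers,
impute them from a reference panel using the remaining typed markers, and
score each masked marker by the squared Pearson correlation r^2 between
true genotypes and imputed dosages across target samples; the discordance
rate is 1 - mean r^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .core import GenotypeMatrix, HaplotypePanel, SnpMap


@dataclass(frozen=True)
class CopyingModelParams:
    """epsilon: per-marker miscopy probability; rho: per-interval switch
    probability (constant across intervals)."""

    epsilon: float = 0.01
    rho: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 < self.epsilon < 0.5:
            raise ValueError("epsilon must be in (0, 0.5)")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must be in [0, 1)")


@dataclass(frozen=True)
class MaskPlan:
    """Which markers are hidden for evaluation (indices into the SnpMap)."""

    masked_ids: tuple[str, ...]
    masked_idx: np.ndarray
    seed: int
    n_total: int

    @property
    def n_masked(self) -> int:
        return len(self.masked_ids)

    def typed_idx(self) -> np.ndarray:
        mask = np.ones(self.n_total, dtype=bool)
        mask[self.masked_idx] = False
        return np.flatnonzero(mask)


def make_mask(snp_map: SnpMap, n_masked: int, seed: int) -> MaskPlan:
    """Draw a uniform random mask of markers, shared by every panel and
    target population of a run so their accuracies are comparable."""
    total = len(snp_map)
    if not 0 < n_masked < total:
        raise ValueError(f"n_masked must be in (0, {total})")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(total, size=n_masked, replace=False))
    ids = tuple(snp_map.snp_ids[idx])
    return MaskPlan(ids, idx, seed, total)


def _forward_backward(obs: np.ndarray, typed: np.ndarray, ref: np.ndarray,
                      eps: float, rho: float) -> np.ndarray:
    """Posterior over reference rows at every marker (markers x rows).

    ``obs`` holds the target alleles (only entries where ``typed`` is True
    are read); emissions at untyped markers are uniform.
    """
    n_ref, n_mark = ref.shape
    # emission likelihoods, markers x rows
    em = np.ones((n_mark, n_ref))
    t = np.flatnonzero(typed)
    match = ref[:, t].T == obs[t][:, None]
    em[t] = np.where(match, 1.0 - eps, eps)
    fwd = np.empty((n_mark, n_ref))
    scale = np.empty(n_mark)
    f = em[0] / n_ref
    scale[0] = f.sum()
    fwd[0] = f / scale[0]
    for m in range(1, n_mark):
        f = ((1.0 - rho) * fwd[m - 1] + rho / n_ref) * em[m]
        scale[m] = f.sum()
        fwd[m] = f / scale[m]
    bwd = np.empty((n_mark, n_ref))
    bwd[-1] = 1.0
    for m in range(n_mark - 2, -1, -1):
        x = bwd[m + 1] * em[m + 1]
        bwd[m] = ((1.0 - rho) * x + rho * x.mean()) / scale[m + 1]
    post = fwd * bwd
    post /= post.sum(axis=1, keepdims=True)
    return post


def li_stephens_dosage(target_hap: np.ndarray, reference: HaplotypePanel,
                       params: CopyingModelParams, mask: MaskPlan) -> np.ndarray:
    """Posterior allele-1 probability at every masked site of one haplotype.

    The dosage marginalises the copying state: for each reference row the
    emitted allele matches the copied one with probability 1 - epsilon, so
    P(allele 1) = sum_s posterior_s (epsilon + (1 - 2 epsilon) ref_s).
    """
    if reference.n_haplotypes == 0:
        raise ValueError("reference panel is empty")
    if mask.n_total != reference.n_markers:
        raise ValueError("mask and reference marker maps differ")
    target_hap = np.asarray(target_hap)
    if target_hap.shape != (reference.n_markers,):
        raise ValueError("target haplotype length does not match the reference map")
    typed = np.ones(reference.n_markers, dtype=bool)
    typed[mask.masked_idx] = False
    post = _forward_backward(target_hap, typed, reference.values,
                             params.epsilon, params.rho)
    ref_masked = reference.values[:, mask.masked_idx].astype(float)
    p_allele1 = params.epsilon + (1.0 - 2.0 * params.epsilon) * ref_masked
    return (post[mask.masked_idx] * p_allele1.T).sum(axis=1)


def impute_targets(target: HaplotypePanel, reference: HaplotypePanel,
                   params: CopyingModelParams, mask: MaskPlan) -> pd.DataFrame:
    """Genotype dosages (0..2) for every target sample at the masked markers.

    Target and reference sample sets must be disjoint — imputing samples
    that sit in their own reference panel would overfit.
    """
    overlap = set(target.sample_ids) & set(reference.sample_ids)
    if overlap:
        raise ValueError(f"overfitting guard: samples in both target and "
                         f"reference: {sorted(overlap)[:5]}")
    if not target.snp_map.equals(reference.snp_map):
        raise ValueError("target and reference marker maps differ")
    rows = np.empty((target.n_samples, mask.n_masked))
    for i in range(target.n_samples):
        d1 = li_stephens_dosage(target.values[2 * i], reference, params, mask)
        d2 = li_stephens_dosage(target.values[2 * i + 1], reference, params, mask)
        rows[i] = d1 + d2
    return pd.DataFrame(rows, index=target.sample_ids, columns=list(mask.masked_ids))


@dataclass
class ImputationEvalResult:
    """Accuracy of one (target population, reference panel) evaluation."""

    target_population: str
    panel_name: str
    r2_per_marker: pd.Series
    n_eval: int
    n_skipped: int
    mean_r2: float
    discordance: float


def evaluate_discordance(truth: GenotypeMatrix, dosages: pd.DataFrame,
                         target_population: str = "", panel_name: str = "",
                         pooled: bool = False) -> ImputationEvalResult:
    """Score imputed dosages against true genotypes at the masked markers.

    Per masked marker, r^2 is the squared Pearson correlation between
    genotype and dosage across samples; markers where either side has zero
    variance are skipped and counted. Discordance = 1 - mean r^2. With
    ``pooled=True`` a single r^2 over all (marker, sample) pairs is used
    instead.
    """
    ids = list(dosages.columns)
    id_to_col = {s: j for j, s in enumerate(truth.snp_map.snp_ids)}
    missing = [s for s in ids if s not in id_to_col]
    if missing:
        raise ValueError(f"markers absent from truth: {missing[:5]}")
    if list(dosages.index) != list(truth.sample_ids):
        raise ValueError("dosage and truth sample sets differ")
    g = truth.values[:, [id_to_col[s] for s in ids]].astype(float)
    d = dosages.to_numpy()
    if pooled:
        gv, dv = g.ravel(), d.ravel()
        if gv.std() == 0 or dv.std() == 0:
            raise ValueError("zero variance in pooled evaluation")
        r2 = float(np.corrcoef(gv, dv)[0, 1] ** 2)
        series = pd.Series(dtype=float)
        res = ImputationEvalResult(target_population, panel_name, series,
                                   len(ids), 0, r2, 1.0 - r2)
        return res
    r2s, skipped = {}, 0
    for j, snp in enumerate(ids):
        gj, dj = g[:, j], d[:, j]
        if gj.std() == 0 or dj.std() == 0:
            skipped += 1
            continue
        r2s[snp] = float(np.corrcoef(gj, dj)[0, 1] ** 2)
    if not r2s:
        raise ValueError("no evaluable markers (all zero-variance)")
    series = pd.Series(r2s)
    mean_r2 = float(series.mean())
    return ImputationEvalResult(target_population, panel_name, series,
                                len(series), skipped, mean_r2, 1.0 - mean_r2)


def panel_comparison(targets: Mapping[str, HaplotypePanel],
                     panels: Mapping[str, HaplotypePanel],
                     params: CopyingModelParams, mask: MaskPlan,
                     pooled: bool = False) -> pd.DataFrame:
    """Discordance for the full cross of target populations x reference
    panels (rows: targets, columns: panels). Combined panels are built by
    the caller with :meth:`HaplotypePanel.concat`."""
    out = pd.DataFrame(index=list(targets), columns=list(panels), dtype=float)
    for tname, tpanel in targets.items():
        truth = tpanel.to_genotypes()
        for pname, ref in panels.items():
            dosages = impute_targets(tpanel, ref, params, mask)
            res = evaluate_discordance(truth, dosages, tname, pname, pooled=pooled)
            out.loc[tname, pname] = res.discordance
    return out
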