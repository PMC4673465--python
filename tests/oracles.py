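"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — enumeration and closed forms only —
and shares no code with the package implementation it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def hwe_exact_pvalue_enumeration(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact HWE p-value by enumerating every genotype configuration
    compatible with the observed allele counts."""
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n - n_a
    if min(n_a, n_b) == 0:
        return 1.0
    # weight of a configuration with h heterozygotes (conditional kernel)
    def weight(h):
        aa = (n_a - h) // 2
        bb = (n_b - h) // 2
        return (2 ** h) * math.comb(n, h) * math.comb(n - h, aa)
    hets = [h for h in range(min(n_a, n_b) + 1) if (n_a - h) % 2 == 0]
    weights = {h: weight(h) for h in hets}
    total = sum(weights.values())
    obs = weights[n_ab]
    return sum(w for w in weights.values() if w <= obs) / total


def binomial_upper_tail(count: int, n: int, p: float) -> float:
    """P(X >= count) for X ~ Binomial(n, p), by direct summation."""
    return sum(math.comb(n, k) * p ** k * (1 - p) ** (n - k)
               for k in range(count, n + 1))


def two_pop_fst_hthhs(p1: float, p2: float) -> float:
    """(H_T - H_S)/H_T computed literally from heterozygosities."""
    pbar = (p1 + p2) / 2
    ht = 2 * pbar * (1 - pbar)
    hs = (2 * p1 * (1 - p1) + 2 * p2 * (1 - p2)) / 2
    if ht == 0:
        return 0.0
    return (ht - hs) / ht


def li_stephens_dosage_paths(target, typed, ref, eps, rho, masked_idx):
    """Masked-site dosages by summing over every copying path explicitly."""
    ref = np.asarray(ref)
    n_ref, n_mark = ref.shape
    dosage_num = np.zeros(len(masked_idx))
    total = 0.0
    for path in itertools.product(range(n_ref), repeat=n_mark):
        w = 1.0 / n_ref
        for m in range(1, n_mark):
            stay = 1.0 - rho + rho / n_ref
            w *= stay if path[m] == path[m - 1] else rho / n_ref
        for m in range(n_mark):
            if typed[m]:
                w *= (1.0 - eps) if ref[path[m], m] == target[m] else eps
        total += w
        for k, m in enumerate(masked_idx):
            dosage_num[k] += w * (eps + (1.0 - 2.0 * eps) * ref[path[m], m])
    return dosage_num / total


def balding_nichols_mean_fst_oracle(F: float, n_haplotypes: int,
                                    n_markers: int, seed: int) -> float:
    """Monte-Carlo expectation of the mean Nei two-population F_ST over
    sample allele frequencies under the Balding–Nichols model."""
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.05, 0.95, n_markers)
    a = p * (1 - F) / F
    b = (1 - p) * (1 - F) / F
    p1 = rng.beta(a, b)
    p2 = rng.beta(a, b)
    f1 = rng.binomial(n_haplotypes, p1) / n_haplotypes
    f2 = rng.binomial(n_haplotypes, p2) / n_haplotypes
    pbar = (f1 + f2) / 2
    den = 4 * pbar * (1 - pbar)
    fst = np.where(den > 0, (f1 - f2) ** 2 / np.where(den > 0, den, 1), 0.0)
    return float(fst.mean())
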