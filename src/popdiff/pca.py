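"""Population-structure ordination.

Two complementary views: a subject-level PCA of standardized genotypes (the
smartPCA construction: per-marker centering, scaling by a shrunk binomial
standard deviation, missing entries zeroed after centering), and a
population-level principal coordinates analysis (classical MDS) of a K x K
F_ST distance matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix
from .fst import FstMatrix


@dataclass
class PcaResult:
    """Coordinates and eigenvalues of one ordination.

    ``entity_kind`` is "sample" or "population"; ``negative_eigenvalue_mass``
    is the summed magnitude of discarded negative PCoA eigenvalues (0 for
    PCA), a diagnostic of how non-Euclidean the input distances were.
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    entity_kind: str
    n_markers: int | None = None
    negative_eigenvalue_mass: float = 0.0

    def __post_init__(self) -> None:
        ev = np.asarray(self.eigenvalues, dtype=float)
        if np.any(np.diff(ev) > 1e-9):
            raise ValueError("eigenvalues must be non-increasing")
        self.eigenvalues = ev


def standardize_genotypes(g: GenotypeMatrix, shrink: bool = True
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Center and scale genotypes per marker; returns (matrix, kept_indices).

    Scaling uses sqrt(p(1-p)) with the shrunk frequency estimate
    p = (1 + sum g) / (2 + 2 n_called) by default (plain p with
    ``shrink=False``). Missing entries become 0 after centering; markers
    that are monomorphic among called samples are dropped.
    """
    if g.n_samples < 2:
        raise ValueError("need at least two samples")
    vals = g.values.astype(float)
    called = g.values != MISSING
    n_called = called.sum(axis=0)
    total = np.where(called, vals, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(n_called > 0, total / n_called, 0.0)
        if shrink:
            p = (1.0 + total) / (2.0 + 2.0 * n_called)
        else:
            p = np.where(n_called > 0, total / (2.0 * n_called), 0.0)
    # a marker is informative if called genotypes actually vary
    varies = np.zeros(g.n_markers, dtype=bool)
    for j in range(g.n_markers):
        col = vals[called[:, j], j]
        varies[j] = col.size > 0 and not np.all(col == col[0])
    scale = np.sqrt(p * (1.0 - p))
    keep = varies & (scale > 0) & (n_called > 0)
    x = np.where(called, vals - mean, 0.0)[:, keep] / scale[keep]
    return x, np.flatnonzero(keep)


def _fix_signs(scores: np.ndarray, loadings: np.ndarray | None = None) -> None:
    """Make each component's largest-magnitude loading (or coordinate)
    positive, in place."""
    ref = loadings if loadings is not None else scores
    for j in range(scores.shape[1]):
        i = np.argmax(np.abs(ref[:, j]))
        if ref[i, j] < 0:
            scores[:, j] *= -1
            if loadings is not None:
                loadings[:, j] *= -1


def subject_pca(g: GenotypeMatrix, n_components: int = 10,
                shrink: bool = True) -> PcaResult:
    """Principal components of the standardized genotype matrix.

    Coordinates are the sample scores U S of the SVD of the standardized
    matrix; eigenvalues are those of the sample covariance (S^2 / (n-1)).
    """
    if g.n_samples < 2:
        raise ValueError("need at least two samples for PCA")
    if n_components >= g.n_samples:
        raise ValueError("n_components must be smaller than the sample count")
    x, kept = standardize_genotypes(g, shrink=shrink)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    k = min(n_components, len(s))
    scores = u[:, :k] * s[:k]
    loadings = vt[:k].T.copy()
    _fix_signs(scores, loadings)
    eigvals = s[:k] ** 2 / (g.n_samples - 1)
    coords = pd.DataFrame(scores, index=g.sample_ids,
                          columns=[f"PC{i + 1}" for i in range(k)])
    coords.insert(0, "population", g.populations)
    return PcaResult(coords, eigvals, "sample", n_markers=len(kept))


def population_pcoa(d: FstMatrix, n_components: int = 2) -> PcaResult:
    """Classical MDS of a population distance matrix.

    Double-centers the elementwise-squared distances,
    B = -1/2 C D(2) C, and embeds on the positive eigenpairs. Negative
    eigenvalues (F_ST matrices are generally non-Euclidean) are discarded
    and their summed magnitude reported as a diagnostic.
    """
    K = len(d.populations)
    if n_components >= K:
        raise ValueError("n_components must be smaller than the number of populations")
    dist = d.values
    c = np.eye(K) - np.ones((K, K)) / K
    b = -0.5 * c @ (dist ** 2) @ c
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = 1e-12 * max(1.0, abs(eigvals[0]))
    positive = eigvals > tol
    neg_mass = float(-eigvals[eigvals < -tol].sum())
    k = min(n_components, int(positive.sum()))
    vals = eigvals[:k]
    coords = eigvecs[:, :k] * np.sqrt(vals)
    _fix_signs(coords)
    frame = pd.DataFrame(coords, index=d.populations,
                         columns=[f"PC{i + 1}" for i in range(k)])
    return PcaResult(frame, vals, "population",
                     negative_eigenvalue_mass=neg_mass)


def average_population_coords(pca: PcaResult,
                              labels: Sequence[str] | None = None) -> PcaResult:
    """Collapse a sample-level PCA to one coordinate per population by
    averaging the sample coordinates component-wise."""
    if pca.entity_kind != "sample":
        raise ValueError("expected a sample-level PCA result")
    coords = pca.coordinates
    if labels is not None:
        coords = coords.drop(columns="population", errors="ignore")
        coords = coords.assign(population=list(labels))
    elif "population" not in coords.columns:
        raise ValueError("no population labels available")
    means = coords.groupby("population", sort=False).mean()
    return PcaResult(means, pca.eigenvalues, "population",
                     n_markers=pca.n_markers)
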