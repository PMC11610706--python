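"""Hierarchical clustering of preprocessed imino-region spectra.

The screen sorted spectra into classes both by manual inspection and by
computer clustering; this module implements the computational route —
pairwise distances between 0–1-scaled spectra on a common ppm grid,
agglomerative clustering, and chance-corrected agreement (adjusted Rand
index, purity) between clusters and rule-based class labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import adjusted_rand_score, silhouette_score

from .spectra import Spectrum

__all__ = [
    "ClusteringResult",
    "spectra_distance_matrix",
    "hierarchical_cluster",
    "choose_k_silhouette",
    "cluster_class_agreement",
]

_METRICS = {"euclidean", "correlation"}
_LINKAGES = {"average", "complete", "ward"}


@dataclass
class ClusteringResult:
    seq_ids: list[str]
    distance_matrix: np.ndarray
    linkage_record: np.ndarray  # scipy merge history
    labels: np.ndarray  # cluster ids 1..k
    metric: str
    linkage: str
    k: int


def spectra_distance_matrix(
    spectra: list[Spectrum], metric: str = "euclidean"
) -> np.ndarray:
    """Pairwise distance matrix over spectra sharing one ppm grid.

    ``correlation`` distance is 1 − Pearson r, which is invariant to affine
    rescaling of any spectrum's intensities.
    """
    if metric not in _METRICS:
        raise ValueError(f"metric must be one of {sorted(_METRICS)}")
    if len(spectra) < 2:
        raise ValueError("need at least two spectra")
    grid = spectra[0].ppm
    for s in spectra[1:]:
        if s.ppm.shape != grid.shape or not np.allclose(s.ppm, grid):
            raise ValueError(
                "spectra must share one common ppm grid; resample first"
            )
    X = np.vstack([s.intensity for s in spectra])
    return squareform(pdist(X, metric=metric))


def hierarchical_cluster(
    d: np.ndarray, linkage: str = "average", k: int = 2
) -> ClusteringResult:
    """Deterministic agglomerative clustering of a precomputed distance matrix.

    Scipy merges the minimum-distance pair at each step, breaking ties by
    the lowest pair index, so fixed inputs give identical labels across runs.
    """
    if linkage not in _LINKAGES:
        raise ValueError(f"linkage must be one of {sorted(_LINKAGES)}")
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n) or not np.allclose(d, d.T) or np.any(np.diag(d) != 0):
        raise ValueError("d must be a symmetric matrix with zero diagonal")
    if not 2 <= k <= n:
        raise ValueError(f"k must be in [2, {n}], got {k}")
    Z = hierarchy.linkage(squareform(d, checks=False), method=linkage)
    # cut after exactly n-k merges: unlike a height cut, this yields k
    # clusters even when several merges share one height (ties)
    labels = hierarchy.cut_tree(Z, n_clusters=k).ravel() + 1
    return ClusteringResult(
        seq_ids=[str(i) for i in range(n)],
        distance_matrix=d,
        linkage_record=Z,
        labels=np.asarray(labels),
        metric="precomputed",
        linkage=linkage,
        k=int(labels.max()),
    )


def choose_k_silhouette(
    d: np.ndarray, linkage: str = "average", k_min: int = 2, k_max: int = 15
) -> int:
    """Number of clusters maximizing the silhouette score (precomputed
    distances); ties go to the smaller k."""
    n = d.shape[0]
    k_max = min(k_max, n - 1)
    best_k, best_score = k_min, -np.inf
    for k in range(k_min, k_max + 1):
        labels = hierarchical_cluster(d, linkage=linkage, k=k).labels
        if len(np.unique(labels)) < 2:
            continue
        score = silhouette_score(d, labels, metric="precomputed")
        if score > best_score:
            best_k, best_score = k, score
    return best_k


def cluster_class_agreement(labels, truth) -> dict[str, float]:
    """Adjusted Rand index and purity of clusters against class labels.

    Purity is the fraction of items sitting in the majority class of their
    cluster; ARI is chance-corrected (0 expected for random labels, 1 for a
    perfect match).
    """
    labels = np.asarray(labels)
    truth = np.asarray(truth)
    if labels.shape != truth.shape:
        raise ValueError("labels and truth must have equal length")
    if np.unique(truth).size < 2:
        raise ValueError("need at least two distinct truth labels")
    ari = float(adjusted_rand_score(truth, labels))
    purity = 0.0
    for c in np.unique(labels):
        members = truth[labels == c]
        _, counts = np.unique(members, return_counts=True)
        purity += counts.max()
    purity /= labels.size
    return {"ari": ari, "purity": float(purity)}
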