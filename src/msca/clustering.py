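"""Ratio-Cut spectral clustering of a fused sample network, plus evaluation.

The Ratio-Cut relaxation embeds the samples in the eigenvectors of the
unnormalized graph Laplacian L = D - W belonging to its c smallest
eigenvalues and discretizes with k-means. Partitions are scored with the
Hubert-Arabie adjusted Rand index against a reference labelling and with the
mean silhouette width on the similarity network itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score
from sklearn.metrics import silhouette_score as _sk_silhouette

from .fusion import FusedNetwork
from .representation import AffinityMatrix

__all__ = [
    "ClusteringResult",
    "ratio_cut_spectral",
    "ratio_cut_objective",
    "adjusted_rand_index",
    "silhouette_score",
    "select_num_clusters",
    "RatioCutSpectralClustering",
]


@dataclass
class ClusteringResult:
    """Partition of the samples: integer labels in 1..num_clusters."""

    labels: np.ndarray
    num_clusters: int
    eigenvalues: np.ndarray
    seed: int
    sample_ids: list[str] | None = None


def _as_similarity(W) -> np.ndarray:
    if isinstance(W, AffinityMatrix):
        return W.W
    if isinstance(W, FusedNetwork):
        return W.W_hash
    return np.asarray(W, dtype=float)


def _ids_of(W) -> list[str] | None:
    if isinstance(W, (AffinityMatrix, FusedNetwork)):
        return list(W.sample_ids)
    return None


def spectral_embedding(W, n_components: int) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvectors of the c smallest eigenvalues of L = D - W.

    Eigenvector signs are fixed deterministically (largest-magnitude entry
    positive) so repeated runs and permuted inputs give reproducible
    embeddings up to the permutation.
    """
    M = _as_similarity(W)
    L = np.diag(M.sum(axis=1)) - M
    L = (L + L.T) / 2.0  # guard symmetry against rounding
    evals, evecs = np.linalg.eigh(L)
    U = evecs[:, :n_components].copy()
    for j in range(U.shape[1]):
        i = int(np.argmax(np.abs(U[:, j])))
        if U[i, j] < 0:
            U[:, j] = -U[:, j]
    return evals[:n_components], U


def ratio_cut_spectral(
    W,
    num_clusters: int,
    seed: int = 0,
    n_init: int = 50,
) -> ClusteringResult:
    """Ratio-Cut spectral clustering on a symmetric nonnegative similarity.

    Parameters
    ----------
    W : array, AffinityMatrix or FusedNetwork
    num_clusters : int
        Number of clusters c, with 2 <= c <= n - 1.
    seed : int
        Seeds the k-means step (all ``n_init`` restarts).
    """
    M = _as_similarity(W)
    n = M.shape[0]
    if not 2 <= num_clusters <= n - 1:
        raise ValueError(f"num_clusters must lie in [2, {n - 1}], got {num_clusters}")
    evals, U = spectral_embedding(M, num_clusters)
    km = KMeans(
        n_clusters=num_clusters, n_init=n_init, random_state=int(seed) % (2**31)
    ).fit(U)
    labels = km.labels_.astype(int) + 1  # 1-based per the ClusteringResult contract
    if num_clusters == 2:
        # Hagen-Kahng refinement: also sweep all threshold cuts along the
        # Fiedler ordering and keep the partition with the lower Ratio-Cut
        # objective (k-means minimizes inertia, not the cut itself)
        order = np.argsort(U[:, 1], kind="stable")
        best_obj = ratio_cut_objective(M, labels)
        for split in range(1, n):
            cand = np.ones(n, dtype=int)
            cand[order[:split]] = 2
            obj = ratio_cut_objective(M, cand)
            if obj < best_obj - 1e-12:
                best_obj = obj
                labels = cand
    return ClusteringResult(
        labels=labels,
        num_clusters=num_clusters,
        eigenvalues=evals,
        seed=seed,
        sample_ids=_ids_of(W),
    )


def ratio_cut_objective(W, labels) -> float:
    """Ratio-Cut value sum_c cut(C, V \\ C) / |C| of a partition."""
    M = _as_similarity(W)
    labels = np.asarray(labels)
    total = 0.0
    for c in np.unique(labels):
        inside = labels == c
        total += M[inside][:, ~inside].sum() / inside.sum()
    return float(total)


def adjusted_rand_index(a, b) -> float:
    """Hubert-Arabie adjusted Rand index between two labelings."""
    a = np.asarray(a).ravel()
    b = np.asarray(b).ravel()
    if a.shape != b.shape:
        raise ValueError(f"label lists differ in length: {a.size} vs {b.size}")
    return float(adjusted_rand_score(a, b))


def similarity_to_dissimilarity(W) -> np.ndarray:
    """d(i, j) = 1 - W(i, j) / max(W), with a zero diagonal."""
    M = _as_similarity(W)
    top = M.max()
    if top <= 0:
        raise ValueError("similarity matrix has no positive entries")
    D = 1.0 - M / top
    np.fill_diagonal(D, 0.0)
    return D


def silhouette_score(W, labels) -> float:
    """Mean silhouette width of a partition on a similarity network.

    Similarities are turned into dissimilarities d = 1 - W/max(W); members of
    singleton clusters contribute silhouette 0.
    """
    labels = np.asarray(labels).ravel()
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("silhouette needs at least 2 clusters")
    D = similarity_to_dissimilarity(W)
    if labels.size != D.shape[0]:
        raise ValueError("labels length does not match the similarity matrix")
    return float(_sk_silhouette(D, labels, metric="precomputed"))


def select_num_clusters(W, c_min: int, c_max: int, seed: int = 0) -> int:
    """Pick the cluster count in [c_min, c_max] maximizing mean silhouette.

    Each candidate c is clustered with :func:`ratio_cut_spectral` and scored;
    ties go to the smaller c. A fully degenerate similarity (all candidates
    tie) returns ``c_min`` with a warning.
    """
    M = _as_similarity(W)
    n = M.shape[0]
    if not 2 <= c_min <= c_max <= n - 1:
        raise ValueError(f"need 2 <= c_min <= c_max <= {n - 1}")
    scores = []
    for c in range(c_min, c_max + 1):
        labels = ratio_cut_spectral(M, c, seed=seed).labels
        scores.append(silhouette_score(M, labels))
    scores = np.asarray(scores)
    if c_max > c_min and float(scores.max() - scores.min()) < 1e-12:
        warnings.warn(
            "silhouette cannot distinguish candidate cluster counts; "
            "returning the smallest",
            RuntimeWarning,
            stacklevel=2,
        )
    best = int(np.argmax(scores))  # argmax takes the first maximum -> smaller c
    return c_min + best


class RatioCutSpectralClustering(BaseEstimator, ClusterMixin):
    """Ratio-Cut spectral clustering with a precomputed similarity matrix.

    ``fit(W)`` expects the symmetric nonnegative n x n similarity itself
    (analogous to ``SpectralClustering(affinity="precomputed")``); cluster
    labels in 1..n_clusters are exposed as ``labels_``.
    """

    def __init__(self, n_clusters: int = 3, random_state: int = 0, n_init: int = 50):
        self.n_clusters = n_clusters
        self.random_state = random_state
        self.n_init = n_init

    def fit(self, X, y=None):
        result = ratio_cut_spectral(
            X, self.n_clusters, seed=self.random_state, n_init=self.n_init
        )
        self.result_ = result
        self.labels_ = result.labels
        self.eigenvalues_ = result.eigenvalues
        return self
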