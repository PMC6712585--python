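"""Synthetic multi-view benchmark generator with planted cluster structure.

The default design mirrors a two-view, 90-sample benchmark with three planted
clusters of 30 samples each, in which every single view is blind to one
cluster boundary: view 1 cannot distinguish clusters 2 and 3, view 2 cannot
distinguish clusters 1 and 2. Only by combining the views are all three
clusters separable, which is exactly the regime cross-view fusion is meant to
resolve.

Each view is built as a low-rank signal: the clusters a view *can* separate
(its "effective groups" after applying the view's merge plan) receive
mutually independent low-dimensional loadings embedded into the view's
feature space through random orthonormal bases. Two heterogeneity regimes
are provided:

``single-subspace``
    every effective group is an isotropic Gaussian cloud inside one affine
    low-dimensional subspace (weak heterogeneity): merged clusters share one
    cloud and are truly indistinguishable within that view;
``multi-manifold``
    every cluster lies on its own curved one-dimensional manifold (an arc
    with drift). Clusters a view merges share the arc plane but drift along
    cluster-specific orthogonal directions, so their manifolds cross near
    the middle of the arc: Euclidean proximity no longer tracks manifold
    membership there and pairwise-distance methods lose that cluster
    boundary, while the manifolds remain distinct low-dimensional subspaces
    that representation-based similarity can still resolve (strong
    heterogeneity).

Measurement noise is additive Gaussian with standard deviation
``noise_frac`` times the elementwise standard deviation of the signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .clustering import adjusted_rand_index, ratio_cut_spectral
from .representation import OmicsView, default_k_neighbors

__all__ = [
    "SyntheticSpec",
    "MultiViewDataset",
    "generate_multiview",
    "single_view_ceiling",
    "DEFAULT_MERGE_PLAN",
]

# view 1 merges clusters {2, 3}; view 2 merges clusters {1, 2} (1-based)
DEFAULT_MERGE_PLAN: list[list[list[int]]] = [[[2, 3]], [[1, 2]]]


@dataclass
class SyntheticSpec:
    """Parameters of the planted multi-view benchmark.

    ``view_merge_plan`` holds, per view, the groups of cluster indices
    (1-based) that view cannot distinguish; clusters inside one group share a
    subspace/manifold in that view. The plan must leave every cluster pair
    separable by at least one view.
    """

    n_per_cluster: int = 30
    n_clusters: int = 3
    view_merge_plan: list[list[list[int]]] = field(
        default_factory=lambda: [[list(g) for g in plan] for plan in DEFAULT_MERGE_PLAN]
    )
    n_features: tuple[int, ...] = (500, 300)
    heterogeneity: str = "multi-manifold"
    noise_frac: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 2 or self.n_per_cluster < 2:
            raise ValueError("need at least 2 clusters with at least 2 samples each")
        if not 0.0 <= self.noise_frac <= 1.0:
            raise ValueError("noise_frac must lie in [0, 1]")
        if self.heterogeneity not in ("single-subspace", "multi-manifold"):
            raise ValueError(
                "heterogeneity must be 'single-subspace' or 'multi-manifold'"
            )
        if len(self.n_features) != len(self.view_merge_plan):
            raise ValueError("n_features and view_merge_plan must have one entry per view")
        for plan in self.view_merge_plan:
            for group in plan:
                if any(not 1 <= c <= self.n_clusters for c in group):
                    raise ValueError(f"merge group {group} names an unknown cluster")
        self._check_feasible()

    @property
    def n_views(self) -> int:
        return len(self.view_merge_plan)

    @property
    def n_samples(self) -> int:
        return self.n_clusters * self.n_per_cluster

    def effective_groups(self, view_index: int) -> list[list[int]]:
        """Partition of clusters as seen by one view (merge plan applied)."""
        parent = list(range(self.n_clusters + 1))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for group in self.view_merge_plan[view_index]:
            root = find(group[0])
            for c in group[1:]:
                parent[find(c)] = root
        groups: dict[int, list[int]] = {}
        for c in range(1, self.n_clusters + 1):
            groups.setdefault(find(c), []).append(c)
        return [sorted(g) for g in sorted(groups.values())]

    def _check_feasible(self) -> None:
        for a in range(1, self.n_clusters + 1):
            for b in range(a + 1, self.n_clusters + 1):
                separable = any(
                    not any(a in g and b in g for g in self.effective_groups(v))
                    for v in range(self.n_views)
                )
                if not separable:
                    raise ValueError(
                        f"clusters {a} and {b} are merged in every view; "
                        "no combination of views can distinguish them"
                    )


@dataclass
class MultiViewDataset:
    views: list[OmicsView]
    true_labels: np.ndarray
    spec: SyntheticSpec


_LOADING_DIM = 4  # per-cluster subspace dimension (offset, 2 arc, 1 drift)
_OFFSET = 3.0  # distance of each group's centre from the origin, in loading units
_ARC_RADIUS = 1.5
_ARC_SPAN = 1.2 * np.pi
_DRIFT = 2.0
_JITTER = 0.05


def _arc_plane_loadings(t: np.ndarray) -> np.ndarray:
    """Offset + arc coordinates (3 x n) shared by the clusters of one group."""
    theta = _ARC_SPAN * t
    return np.vstack(
        [
            np.full(t.size, _OFFSET),
            _ARC_RADIUS * np.cos(theta),
            _ARC_RADIUS * np.sin(theta),
        ]
    )


def _fill_group_single_subspace(
    rng: np.random.Generator, X: np.ndarray, cols: np.ndarray
) -> None:
    """Merged clusters share one Gaussian cloud in a common affine subspace."""
    n = int(cols.sum())
    basis, _ = np.linalg.qr(rng.normal(size=(X.shape[0], _LOADING_DIM)))
    C = rng.normal(size=(_LOADING_DIM, n))
    C[0] += _OFFSET
    X[:, cols] = basis @ C


def _fill_group_multi_manifold(
    rng: np.random.Generator,
    X: np.ndarray,
    member_cols: list[np.ndarray],
) -> None:
    """Each cluster of the group gets its own arc-with-drift manifold.

    All clusters of the group share the 3-dimensional offset + arc plane;
    each drifts along its own extra orthonormal direction, with drift
    magnitude vanishing mid-arc. Manifolds of merged clusters therefore
    cross near the arc middle (Euclidean neighbours mix there) while each
    remains a distinct 4-dimensional subspace.
    """
    h = X.shape[0]
    n_clusters = len(member_cols)
    basis, _ = np.linalg.qr(rng.normal(size=(h, 3 + n_clusters)))
    shared, drifts = basis[:, :3], basis[:, 3:]
    for c, cols in enumerate(member_cols):
        n = int(cols.sum())
        t = rng.uniform(size=n)
        C3 = _arc_plane_loadings(t) + rng.normal(scale=_JITTER, size=(3, n))
        drift = _DRIFT * (2.0 * t - 1.0) + rng.normal(scale=_JITTER, size=n)
        X[:, cols] = shared @ C3 + drifts[:, c : c + 1] @ drift[None, :]


def generate_multiview(spec: SyntheticSpec) -> MultiViewDataset:
    """Draw a multi-view dataset with the planted structure of ``spec``.

    Deterministic for a fixed spec (including its seed): every view's bases,
    loadings and noise are drawn from one seeded generator in a fixed order.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    labels = np.repeat(np.arange(1, spec.n_clusters + 1), spec.n_per_cluster)
    sample_ids = [f"S{i + 1:03d}" for i in range(n)]

    views = []
    for v in range(spec.n_views):
        h = spec.n_features[v]
        X = np.zeros((h, n))
        for group in spec.effective_groups(v):
            if spec.heterogeneity == "single-subspace":
                cols = np.isin(labels, group)
                _fill_group_single_subspace(rng, X, cols)
            else:
                member_cols = [labels == c for c in group]
                _fill_group_multi_manifold(rng, X, member_cols)
        if spec.noise_frac > 0:
            sigma = spec.noise_frac * X.std()
            X = X + rng.normal(scale=sigma, size=X.shape)
        views.append(OmicsView(values=X, sample_ids=sample_ids, view_name=f"view{v + 1}"))
    return MultiViewDataset(views=views, true_labels=labels, spec=spec)


def gaussian_kernel_affinity(X: np.ndarray, k_neighbors: int | None = None) -> np.ndarray:
    """Pairwise Gaussian kernel on sample columns with local-scaling bandwidth.

    The bandwidth is the median over samples of the mean distance to the
    ``k_neighbors`` nearest neighbours (default: 10% of n, floored at 3), the
    usual local-scaling heuristic that keeps the kernel informative when
    between-cluster and within-cluster distances are on similar scales.
    """
    D = squareform(pdist(np.asarray(X, dtype=float).T))
    n = D.shape[0]
    if k_neighbors is None:
        k_neighbors = default_k_neighbors(n)
    knn_mean = np.sort(D, axis=1)[:, 1 : k_neighbors + 1].mean(axis=1)
    sigma = float(np.median(knn_mean))
    if sigma <= 0:
        sigma = 1.0
    return np.exp(-(D**2) / (2.0 * sigma**2))


def single_view_ceiling(
    dataset: MultiViewDataset, view_index: int, seed: int = 0
) -> float:
    """ARI attainable by spectral clustering of one view's raw similarity.

    Uses the Gaussian kernel of pairwise Euclidean distances (median-distance
    bandwidth) and the planted number of clusters. By construction of the
    merge plans this is bounded away from 1 for any view that merges a
    cluster pair.
    """
    view = dataset.views[view_index]
    W = gaussian_kernel_affinity(view.values)
    result = ratio_cut_spectral(W, dataset.spec.n_clusters, seed=seed)
    return adjusted_rand_index(result.labels, dataset.true_labels)
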