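"""End-to-end multi-view subspace clustering: representation -> fusion -> cut.

`MSCA` is the top-level scikit-learn-style estimator: it learns one
locality-constrained low-rank affinity per view, diffuses the affinities
across views into a fused network, and partitions the fused network with
Ratio-Cut spectral clustering.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

from .clustering import (
    ratio_cut_spectral,
    select_num_clusters,
    silhouette_score,
)
from .fusion import cross_diffuse
from .representation import (
    LocalLowRankRepresentation,
    OmicsView,
    default_k_neighbors,
)

__all__ = ["MSCA", "run_pipeline"]


class MSCA(BaseEstimator, ClusterMixin):
    """Multi-view Subspace Clustering Analysis.

    Parameters
    ----------
    n_clusters : int or "auto"
        Number of sample clusters; "auto" picks the silhouette-maximizing
        count in ``auto_range``.
    k_neighbors : int or None
        KNN size for both the representation support and the diffusion
        kernel; ``None`` uses max(3, round(0.1 * n_samples)).
    lam : float
        Error-term weight of the per-view representation problem.
    fusion_k_neighbors : int or None
        Overrides ``k_neighbors`` for the diffusion kernel only.
    fusion_iters, fusion_tol, renormalize
        Cross-view diffusion schedule.
    zscore, normalize, mu_init, mu_growth, mu_max, max_iter, tol
        Per-view solver preprocessing and LADMAP schedule.
    random_state : int
        Seeds the k-means discretization (the only stochastic step).

    Attributes
    ----------
    labels_ : ndarray
        Cluster label (1..c) per sample.
    affinities_ : list of ndarray
        Per-view learned affinity matrices W^i.
    fused_network_ : ndarray
        The diffused multi-view network W#.
    representations_ : list of LocalLowRankRepresentation
        The fitted per-view estimators (residual histories included).
    n_clusters_ : int
        The cluster count actually used.
    silhouette_ : float
        Mean silhouette of the final partition on W#.
    """

    def __init__(
        self,
        n_clusters: int | str = 3,
        k_neighbors: int | None = None,
        lam: float = 0.5,
        fusion_k_neighbors: int | None = None,
        fusion_iters: int = 30,
        fusion_tol: float = 1e-6,
        renormalize: bool = True,
        zscore: bool = True,
        normalize: bool = True,
        mu_init: float = 1e-2,
        mu_growth: float = 1.1,
        mu_max: float = 1e10,
        max_iter: int = 500,
        tol: float = 1e-6,
        auto_range: tuple[int, int] = (2, 8),
        random_state: int = 0,
    ):
        self.n_clusters = n_clusters
        self.k_neighbors = k_neighbors
        self.lam = lam
        self.fusion_k_neighbors = fusion_k_neighbors
        self.fusion_iters = fusion_iters
        self.fusion_tol = fusion_tol
        self.renormalize = renormalize
        self.zscore = zscore
        self.normalize = normalize
        self.mu_init = mu_init
        self.mu_growth = mu_growth
        self.mu_max = mu_max
        self.max_iter = max_iter
        self.tol = tol
        self.auto_range = auto_range
        self.random_state = random_state

    @staticmethod
    def _to_sample_matrices(views) -> tuple[list[np.ndarray], list[str] | None]:
        """Normalize the input to (n_samples x n_features) arrays."""
        mats, ids = [], None
        for v in views:
            if isinstance(v, OmicsView):
                if ids is None:
                    ids = list(v.sample_ids)
                elif list(v.sample_ids) != ids:
                    raise ValueError(
                        "views disagree on sample identifiers/order; reconcile "
                        "them first (see msca.io.align_views)"
                    )
                mats.append(v.values.T)
            else:
                mats.append(np.asarray(v, dtype=float))
        n = mats[0].shape[0]
        if any(M.shape[0] != n for M in mats):
            raise ValueError("all views must describe the same samples")
        return mats, ids

    def fit(self, X, y=None):
        """Fit on a list of views, each (n_samples, n_features) or OmicsView."""
        mats, ids = self._to_sample_matrices(X)
        if len(mats) < 2:
            raise ValueError("multi-view clustering needs at least 2 views")
        n = mats[0].shape[0]
        k = self.k_neighbors if self.k_neighbors is not None else default_k_neighbors(n)
        k_fuse = self.fusion_k_neighbors if self.fusion_k_neighbors is not None else k

        self.representations_ = []
        self.affinities_ = []
        for M in mats:
            est = LocalLowRankRepresentation(
                k_neighbors=k,
                lam=self.lam,
                zscore=self.zscore,
                normalize=self.normalize,
                mu_init=self.mu_init,
                mu_growth=self.mu_growth,
                mu_max=self.mu_max,
                max_iter=self.max_iter,
                tol=self.tol,
            ).fit(M)
            self.representations_.append(est)
            self.affinities_.append(est.affinity_)

        fused = cross_diffuse(
            self.affinities_,
            k_neighbors=k_fuse,
            max_iter=self.fusion_iters,
            tol=self.fusion_tol,
            renormalize=self.renormalize,
            sample_ids=ids,
        )
        self.fusion_result_ = fused
        self.fused_network_ = fused.W_hash

        if self.n_clusters == "auto":
            c = select_num_clusters(
                self.fused_network_,
                self.auto_range[0],
                min(self.auto_range[1], n - 1),
                seed=self.random_state,
            )
        else:
            c = int(self.n_clusters)
        result = ratio_cut_spectral(fused, c, seed=self.random_state)
        self.clustering_result_ = result
        self.labels_ = result.labels
        self.n_clusters_ = c
        self.sample_ids_ = ids
        self.silhouette_ = silhouette_score(self.fused_network_, self.labels_)
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_


def run_pipeline(config):
    """Execute a full run from a :class:`msca.io.RunConfig`.

    Reads the views, reconciles sample order by identifier, fits
    :class:`MSCA`, and writes labels, the fused network, the per-view
    residual log and the resolved configuration into ``config.output_dir``.
    Returns the fitted estimator.
    """
    import logging
    from pathlib import Path

    from . import io as mio

    log = logging.getLogger("msca")
    views = [mio.read_view(p, transposed=config.transposed) for p in config.view_paths]
    try:
        views = mio.align_views(views)
    except ValueError as exc:
        raise ValueError(f"[input] {exc}") from exc

    model = MSCA(
        n_clusters=config.num_clusters,
        k_neighbors=config.k_neighbors,
        lam=config.lam,
        fusion_iters=config.fusion_iters,
        fusion_tol=config.fusion_tol,
        renormalize=config.renormalize,
        zscore=config.zscore,
        tol=config.solver_tol,
        random_state=config.seed,
    )
    stage = "representation/fusion/clustering"
    try:
        model.fit(views)
    except Exception as exc:
        raise RuntimeError(f"[{stage}] {exc}") from exc

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    ids = views[0].sample_ids
    mio.write_labels(model.labels_, ids, out / "labels.tsv")
    mio.write_matrix(model.fused_network_, ids, out / "fused_network.tsv")
    config.to_yaml(out / "config.yaml")
    with open(out / "solver_log.tsv", "w") as fh:
        fh.write("view\titeration\treconstruction\tcolumn_sum\tz_minus_j\n")
        for v, est in zip(views, model.representations_):
            for i, row in enumerate(est.solution_.residuals, start=1):
                fh.write(f"{v.view_name}\t{i}\t{row[0]:.3e}\t{row[1]:.3e}\t{row[2]:.3e}\n")
            log.info(
                "view %s: %d iterations, converged=%s",
                v.view_name, est.n_iter_, est.converged_,
            )
    if config.dump_intermediates:
        for v, est in zip(views, model.representations_):
            mio.write_matrix(est.representation_, ids, out / f"Z_{v.view_name}.tsv")
            mio.write_matrix(est.affinity_, ids, out / f"W_{v.view_name}.tsv")
        if model.fusion_result_.state is not None:
            for i, P in enumerate(model.fusion_result_.state.P_list, start=1):
                mio.write_matrix(P, ids, out / f"P_view{i}.tsv")
    log.info(
        "clustered %d samples into %d clusters (silhouette %.3f)",
        len(ids), model.n_clusters_, model.silhouette_,
    )
    return model
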