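"""Cross-view diffusion of per-view sample affinities into one fused network.

Each view's affinity W is normalized two ways: a row-stochastic *status*
matrix P carrying the full similarity profile of every sample (with half the
mass held on the diagonal, which damps scale bias between views), and a
row-stochastic *local kernel* S restricted to each sample's K strongest
neighbours. Diffusion then repeatedly passes the average of the other views'
status matrices through each view's local kernel,

    P^i  <-  S^i  ( sum_{k != i} P^k / (m - 1) )  (S^i)^T,

so that similarity supported by a sample's neighbourhoods in several views is
reinforced while discordant, view-specific similarity decays. The fused
network is the average of the final status matrices, symmetrized.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .representation import AffinityMatrix

__all__ = [
    "FusionState",
    "FusedNetwork",
    "full_kernel",
    "local_kernel",
    "cross_diffuse",
    "CrossViewDiffusion",
]

from sklearn.base import BaseEstimator


@dataclass
class FusionState:
    """Per-view diffusion state after ``t`` iterations."""

    P_list: list[np.ndarray]
    S_list: list[np.ndarray]
    m: int
    t: int
    K: int
    history: list[float] = field(default_factory=list)  # max change per iteration
    row_sum_dev: list[float] = field(default_factory=list)  # max |row sum - 1| per iter


@dataclass
class FusedNetwork:
    """Symmetrized average of the converged status matrices (the W# network)."""

    W_hash: np.ndarray
    sample_ids: list[str]
    iterations_used: int
    state: FusionState | None = None


def _as_matrix(W: AffinityMatrix | FusedNetwork | np.ndarray) -> np.ndarray:
    if isinstance(W, AffinityMatrix):
        return W.W
    if isinstance(W, FusedNetwork):
        return W.W_hash
    return np.asarray(W, dtype=float)


def full_kernel(W: AffinityMatrix | np.ndarray) -> np.ndarray:
    """Row-stochastic status matrix P from a symmetric nonnegative affinity.

    P(i, j) = W(i, j) / (2 * sum_{k != i} W(i, k)) off the diagonal and
    P(i, i) = 1/2, so each row sums to exactly 1 with half the mass kept on
    the sample itself.
    """
    M = _as_matrix(W)
    n = M.shape[0]
    off = M.copy()
    np.fill_diagonal(off, 0.0)
    denom = off.sum(axis=1)
    if np.any(denom <= 0):
        isolated = int(np.nonzero(denom <= 0)[0][0])
        ids = W.sample_ids if isinstance(W, AffinityMatrix) else None
        name = ids[isolated] if ids else f"index {isolated}"
        raise ValueError(
            f"sample {name} has no positive off-diagonal affinity; "
            "the status matrix is undefined for isolated samples"
        )
    P = off / (2.0 * denom[:, None])
    np.fill_diagonal(P, 0.5)
    return P


def local_kernel(W: AffinityMatrix | np.ndarray, k_neighbors: int) -> np.ndarray:
    """Row-stochastic kernel restricted to each sample's K strongest neighbours.

    N_i is the set of K samples with largest affinity to i (self excluded,
    ties broken by ascending index); S(i, j) = W(i, j) / sum_{k in N_i} W(i, k)
    for j in N_i and 0 elsewhere. A row whose neighbourhood carries zero total
    affinity is zeroed with a warning rather than rejected: the sample can
    still receive similarity through other views during diffusion.
    """
    M = _as_matrix(W)
    n = M.shape[0]
    if not 1 <= k_neighbors <= n - 1:
        raise ValueError(
            f"k_neighbors must lie in [1, n-1] = [1, {n - 1}], got {k_neighbors}"
        )
    A = M.copy()
    np.fill_diagonal(A, -np.inf)  # self never a neighbour
    # descending affinity, ties by ascending index: stable sort on -A
    order = np.argsort(-A, axis=1, kind="stable")
    S = np.zeros_like(M)
    rows = np.repeat(np.arange(n), k_neighbors)
    cols = order[:, :k_neighbors].ravel()
    S[rows, cols] = M[rows, cols]
    sums = S.sum(axis=1)
    empty = sums <= 0
    if np.any(empty):
        warnings.warn(
            f"{int(empty.sum())} sample(s) have zero affinity over their "
            f"{k_neighbors} nearest neighbours; their kernel rows are zeroed",
            RuntimeWarning,
            stacklevel=2,
        )
        sums[empty] = 1.0
    return S / sums[:, None]


def _renormalize_status(P: np.ndarray) -> np.ndarray:
    """Re-apply the status-matrix transform so P stays row-stochastic."""
    off = P.copy()
    np.fill_diagonal(off, 0.0)
    denom = off.sum(axis=1)
    out = np.zeros_like(P)
    ok = denom > 0
    out[ok] = off[ok] / (2.0 * denom[ok, None])
    d = np.full(P.shape[0], 0.5)
    d[~ok] = 1.0  # a row with no off-diagonal mass keeps all weight on itself
    out[np.diag_indices_from(out)] = d
    return out


def cross_diffuse(
    W_list: list[AffinityMatrix | np.ndarray],
    k_neighbors: int,
    max_iter: int = 30,
    tol: float = 1e-6,
    renormalize: bool = True,
    sample_ids: list[str] | None = None,
) -> FusedNetwork:
    """Fuse m >= 2 per-view affinities by cross-view graph diffusion.

    Every iteration updates all views simultaneously from the previous
    iteration's status matrices,

        P_new^i = S^i (sum_{k != i} P^k / (m - 1)) (S^i)^T,

    then (by default) re-applies the status normalization so each P stays
    row-stochastic; the literal un-renormalized iteration is available with
    ``renormalize=False``. Stops when the maximum elementwise change across
    views drops to ``tol`` or after ``max_iter`` iterations; the fused
    network is the average of the final status matrices, symmetrized by
    averaging with its transpose.
    """
    m = len(W_list)
    if m < 2:
        raise ValueError("cross-view diffusion needs at least 2 views (m - 1 > 0)")
    ids: list[str] | None = sample_ids
    mats = []
    for W in W_list:
        if isinstance(W, AffinityMatrix):
            if ids is None:
                ids = W.sample_ids
            elif W.sample_ids != ids:
                raise ValueError("views disagree on sample identifiers/order")
        mats.append(_as_matrix(W))
    n = mats[0].shape[0]
    if any(M.shape != (n, n) for M in mats):
        raise ValueError("all affinity matrices must share the same shape")
    if ids is None:
        ids = [f"S{i}" for i in range(n)]

    P_list = [full_kernel(M) for M in mats]
    S_list = [local_kernel(M, k_neighbors) for M in mats]
    state = FusionState(P_list=P_list, S_list=S_list, m=m, t=0, K=k_neighbors)

    total = sum(P_list)
    t = 0
    for t in range(1, max_iter + 1):
        new_list = []
        for i in range(m):
            avg = (total - P_list[i]) / (m - 1)
            P_new = S_list[i] @ avg @ S_list[i].T
            if renormalize:
                P_new = _renormalize_status(P_new)
            new_list.append(P_new)
        change = max(
            float(np.max(np.abs(new - old))) for new, old in zip(new_list, P_list)
        )
        P_list = new_list
        total = sum(P_list)
        state.P_list = P_list
        state.t = t
        state.history.append(change)
        state.row_sum_dev.append(
            max(float(np.max(np.abs(P.sum(axis=1) - 1.0))) for P in P_list)
        )
        if change <= tol:
            break

    W_hash = total / m
    W_hash = (W_hash + W_hash.T) / 2.0
    return FusedNetwork(W_hash=W_hash, sample_ids=list(ids), iterations_used=t, state=state)


class CrossViewDiffusion(BaseEstimator):
    """Scikit-learn style wrapper around :func:`cross_diffuse`.

    ``fit`` takes a list of per-view sample affinity matrices (each
    n_samples x n_samples) and exposes the fused network as ``fused_network_``.
    """

    def __init__(
        self,
        k_neighbors: int = 3,
        max_iter: int = 30,
        tol: float = 1e-6,
        renormalize: bool = True,
    ):
        self.k_neighbors = k_neighbors
        self.max_iter = max_iter
        self.tol = tol
        self.renormalize = renormalize

    def fit(self, X, y=None):
        result = cross_diffuse(
            list(X),
            k_neighbors=self.k_neighbors,
            max_iter=self.max_iter,
            tol=self.tol,
            renormalize=self.renormalize,
        )
        self.result_ = result
        self.fused_network_ = result.W_hash
        self.status_matrices_ = result.state.P_list if result.state else None
        self.n_iter_ = result.iterations_used
        return self

    def fit_transform(self, X, y=None) -> np.ndarray:
        """Fit on the list of affinities and return the fused network W#."""
        return self.fit(X).fused_network_
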