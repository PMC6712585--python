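"""Locality-constrained low-rank representation of samples within one omics view.

Each sample (column of a features x samples matrix) is expressed as an affine
combination of its K nearest neighbours, with a nuclear-norm penalty on the
coefficient matrix Z and a column-wise l2,1 penalty on the residual E:

    min_{Z,E}  ||Z||_* + lambda * ||E||_{2,1}
    s.t.       X = X Z + E,   Z^T 1 = 1,   Z_ij = 0 outside the KNN support.

The solver is a linearized ADMM with an adaptive penalty (LADMAP): the nuclear
norm is split off into an auxiliary variable J handled by singular-value
thresholding, E has a closed-form column shrinkage, and the Z subproblem is
linearized and projected onto the KNN support. The converged Z is symmetrized
into a nonnegative sample affinity matrix W = (|Z| + |Z^T|) / 2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import squareform, pdist
from sklearn.base import BaseEstimator

__all__ = [
    "OmicsView",
    "NeighborSupport",
    "SolverConfig",
    "RepresentationSolution",
    "AffinityMatrix",
    "knn_adjacency",
    "svt",
    "l21_shrink",
    "solve_lrr",
    "affinity_from_representation",
    "default_k_neighbors",
    "zscore_features",
    "spectral_rescale",
    "LocalLowRankRepresentation",
]


@dataclass
class OmicsView:
    """One data type's measurements: ``values`` is features x samples."""

    values: np.ndarray
    sample_ids: list[str]
    view_name: str = "view"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError(f"view {self.view_name!r}: values must be 2-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"view {self.view_name!r}: non-finite values present")
        if self.values.shape[1] != len(self.sample_ids):
            raise ValueError(
                f"view {self.view_name!r}: {self.values.shape[1]} columns but "
                f"{len(self.sample_ids)} sample identifiers"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError(f"view {self.view_name!r}: duplicate sample identifiers")
        if self.n_samples < 3:
            raise ValueError(f"view {self.view_name!r}: need at least 3 samples")

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def n_features(self) -> int:
        return self.values.shape[0]


@dataclass
class NeighborSupport:
    """Allowed nonzero pattern of Z: ``mask[i, j]`` is True iff sample i may
    carry weight in the representation of sample j (i is a KNN of j).

    The diagonal is always excluded so a sample cannot represent itself.
    """

    mask: np.ndarray
    k_neighbors: int

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        n = self.mask.shape[0]
        if self.mask.shape != (n, n):
            raise ValueError("support mask must be square")
        if np.any(np.diag(self.mask)):
            raise ValueError("self-representation (i, i) must be excluded from the support")
        if not np.all(self.mask.sum(axis=0) >= 1):
            raise ValueError("every sample needs at least one allowed neighbour")

    @property
    def pairs(self) -> set[tuple[int, int]]:
        """The support as a set of 0-based (i, j) index pairs."""
        ii, jj = np.nonzero(self.mask)
        return set(zip(ii.tolist(), jj.tolist()))


@dataclass
class SolverConfig:
    """LADMAP hyper-parameters.

    ``lam`` balances the nuclear norm against the l2,1 error term. ``mu``
    follows the geometric schedule mu <- min(mu_max, mu_growth * mu) from
    ``mu_init``; convergence is declared when all three constraint residuals
    fall below ``tol`` in max-norm.
    """

    lam: float = 0.5
    mu_init: float = 1e-2
    mu_growth: float = 1.1
    mu_max: float = 1e10
    max_iter: int = 500
    tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lam must be positive")
        if self.mu_init <= 0 or self.mu_max <= 0 or self.mu_init > self.mu_max:
            raise ValueError("need 0 < mu_init <= mu_max")
        if self.mu_growth <= 1:
            raise ValueError("mu_growth must exceed 1")
        if self.max_iter < 1 or self.tol <= 0:
            raise ValueError("max_iter >= 1 and tol > 0 required")


@dataclass
class RepresentationSolution:
    """Converged state of the LADMAP solve, with per-iteration residuals."""

    Z: np.ndarray
    E: np.ndarray
    J: np.ndarray
    Y1: np.ndarray
    Y2: np.ndarray
    Y3: np.ndarray
    eta: float
    residuals: np.ndarray  # (iterations, 3): reconstruction, column-sum, Z-J
    converged: bool
    iterations: int
    support: NeighborSupport | None = None


@dataclass
class AffinityMatrix:
    """Symmetric nonnegative sample x sample similarity."""

    W: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        if self.W.ndim != 2 or self.W.shape[0] != self.W.shape[1]:
            raise ValueError("affinity matrix must be square")
        if not self.sample_ids:
            self.sample_ids = [f"S{i}" for i in range(self.W.shape[0])]


def default_k_neighbors(n_samples: int) -> int:
    """Default neighbourhood size: 10% of the sample count, floored at 3."""
    return max(3, round(0.1 * n_samples))


def zscore_features(X: np.ndarray) -> np.ndarray:
    """Per-feature (row-wise) standardization; constant features map to 0."""
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def spectral_rescale(X: np.ndarray) -> np.ndarray:
    """Rescale a features x samples matrix so its spectral norm equals sqrt(n).

    A scalar rescale of X is exactly a reparametrization of ``lam`` (the
    admissible error E scales with X), but it conditions the LADMAP step size
    eta = ||X||_2^2 + n + 1 so that no constraint block dominates the others.
    """
    X = np.asarray(X, dtype=float)
    s = np.linalg.norm(X, 2)
    if s == 0:
        return X.copy()
    return X * (np.sqrt(X.shape[1]) / s)


def knn_adjacency(view: OmicsView | np.ndarray, k_neighbors: int) -> NeighborSupport:
    """K-nearest-neighbour support on pairwise Euclidean distances.

    For every sample j the K samples with smallest distance to j (self
    excluded) are allowed as representers, i.e. ``(i, j)`` enters the support.
    Equal distances are broken by ascending sample index so the support is
    deterministic even with duplicated coordinates.
    """
    X = view.values if isinstance(view, OmicsView) else np.asarray(view, dtype=float)
    n = X.shape[1]
    if not 1 <= k_neighbors <= n - 1:
        raise ValueError(
            f"k_neighbors must lie in [1, n-1] = [1, {n - 1}], got {k_neighbors}"
        )
    D = squareform(pdist(X.T))
    np.fill_diagonal(D, np.inf)  # exclude self
    # stable sort => ties resolved by lower index
    order = np.argsort(D, axis=0, kind="stable")
    mask = np.zeros((n, n), dtype=bool)
    cols = np.repeat(np.arange(n), k_neighbors)
    rows = order[:k_neighbors, :].T.ravel()
    mask[rows, cols] = True
    return NeighborSupport(mask=mask, k_neighbors=k_neighbors)


def svt(M: np.ndarray, tau: float) -> np.ndarray:
    """Singular-value soft-thresholding, the proximal operator of the nuclear
    norm: with M = U diag(s) V^T, returns U diag(max(s - tau, 0)) V^T."""
    if tau < 0:
        raise ValueError("tau must be nonnegative")
    M = np.asarray(M, dtype=float)
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    s = np.maximum(s - tau, 0.0)
    keep = s > 0
    if not np.any(keep):
        return np.zeros_like(M)
    return (U[:, keep] * s[keep]) @ Vt[keep, :]


def l21_shrink(M: np.ndarray, tau: float) -> np.ndarray:
    """Column-wise shrinkage, the proximal operator of the l2,1 norm: column j
    is scaled by max(0, 1 - tau/||m_j||_2) (zeroed when its norm <= tau)."""
    if tau < 0:
        raise ValueError("tau must be nonnegative")
    M = np.asarray(M, dtype=float)
    norms = np.linalg.norm(M, axis=0)
    scale = np.zeros_like(norms)
    pos = norms > tau
    scale[pos] = 1.0 - tau / norms[pos]
    return M * scale


class SolverDivergence(RuntimeError):
    """Raised when non-finite values appear mid-iteration."""


def solve_lrr(
    view: OmicsView | np.ndarray,
    support: NeighborSupport,
    config: SolverConfig | None = None,
) -> RepresentationSolution:
    """Run the LADMAP iteration for the locality-constrained LRR problem.

    Per outer iteration k (penalty mu):

    1. J <- svt(Z + Y3/mu, 1/mu)                      (nuclear-norm block)
    2. E <- l21_shrink(X - X Z + Y1/mu, lam/mu)       (error block)
    3. Z <- Proj_support(Z - H/eta) with
       H = -X^T (X - X Z - E + Y1/mu) - 1 (1^T - 1^T Z + Y2/mu) + (Z - J + Y3/mu)
       and step size eta = ||X||_2^2 + n + 1
    4. multiplier ascent on the three constraints; mu <- min(mu_max, rho * mu)

    Stops when the max-norms of X - XZ - E, 1^T - 1^T Z and Z - J all fall
    below ``config.tol``. Non-convergence within ``max_iter`` returns a
    solution flagged ``converged=False`` together with a warning; divergence
    (non-finite values) raises :class:`SolverDivergence`.
    """
    if config is None:
        config = SolverConfig()
    X = view.values if isinstance(view, OmicsView) else np.asarray(view, dtype=float)
    h, n = X.shape
    mask = support.mask
    if mask.shape != (n, n):
        raise ValueError("support mask size does not match the view")

    spectral = np.linalg.norm(X, 2)
    eta = spectral**2 + n + 1.0

    Z = np.zeros((n, n))
    J = np.zeros((n, n))
    E = np.zeros((h, n))
    Y1 = np.zeros((h, n))
    Y2 = np.zeros((1, n))
    Y3 = np.zeros((n, n))
    mu = config.mu_init
    ones_col = np.ones((n, 1))

    V = X @ Z  # cached X Z, kept in sync with Z
    residuals: list[tuple[float, float, float]] = []
    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        J = svt(Z + Y3 / mu, 1.0 / mu)
        E = l21_shrink(X - V + Y1 / mu, config.lam / mu)

        A = X - V - E + Y1 / mu
        row_def = 1.0 - Z.sum(axis=0, keepdims=True)  # 1^T - 1^T Z
        H = -(X.T @ A) - ones_col @ (row_def + Y2 / mu) + (Z - J + Y3 / mu)
        Z = Z - H / eta
        Z[~mask] = 0.0
        V = X @ Z

        R1 = X - V - E
        r2 = 1.0 - Z.sum(axis=0, keepdims=True)
        R3 = Z - J
        res = (
            float(np.max(np.abs(R1))),
            float(np.max(np.abs(r2))),
            float(np.max(np.abs(R3))),
        )
        if not np.all(np.isfinite(res)):
            names = ("reconstruction", "column-sum", "Z-J")
            bad = [names[i] for i, r in enumerate(res) if not np.isfinite(r)]
            raise SolverDivergence(
                f"non-finite {'/'.join(bad)} residual at iteration {it}"
            )
        residuals.append(res)

        Y1 = Y1 + mu * R1
        Y2 = Y2 + mu * r2
        Y3 = Y3 + mu * R3
        mu = min(config.mu_max, config.mu_growth * mu)

        if max(res) <= config.tol:
            converged = True
            break

    if not converged:
        warnings.warn(
            f"LRR solver did not converge in {config.max_iter} iterations "
            f"(final residuals {residuals[-1]}); returning the last iterate",
            RuntimeWarning,
            stacklevel=2,
        )

    return RepresentationSolution(
        Z=Z,
        E=E,
        J=J,
        Y1=Y1,
        Y2=Y2,
        Y3=Y3,
        eta=eta,
        residuals=np.asarray(residuals),
        converged=converged,
        iterations=it,
        support=support,
    )


def affinity_from_representation(
    solution: RepresentationSolution | np.ndarray,
    sample_ids: list[str] | None = None,
) -> AffinityMatrix:
    """Symmetrize the representation into W = (|Z| + |Z^T|) / 2."""
    Z = solution.Z if isinstance(solution, RepresentationSolution) else np.asarray(solution)
    if not np.all(np.isfinite(Z)):
        raise ValueError("representation contains non-finite values")
    A = np.abs(Z)
    W = (A + A.T) / 2.0
    return AffinityMatrix(W=W, sample_ids=sample_ids or [])


class LocalLowRankRepresentation(BaseEstimator):
    """Sample-affinity learning for one omics view via locality-constrained LRR.

    Parameters
    ----------
    k_neighbors : int or None
        KNN support size; ``None`` uses max(3, round(0.1 * n_samples)).
    lam : float
        Weight of the l2,1 error term.
    zscore : bool
        Standardize each feature across samples before solving.
    normalize : bool
        Rescale the view to unit operating scale (spectral norm sqrt(n))
        before solving; see :func:`spectral_rescale`.
    mu_init, mu_growth, mu_max, max_iter, tol
        LADMAP penalty schedule and stopping rule.

    Attributes
    ----------
    representation_ : ndarray of shape (n_samples, n_samples)
        The converged coefficient matrix Z*.
    affinity_ : ndarray of shape (n_samples, n_samples)
        W = (|Z*| + |Z*^T|) / 2.
    support_ : NeighborSupport
    solution_ : RepresentationSolution
    n_iter_ : int
    converged_ : bool

    Notes
    -----
    Following the scikit-learn convention, ``fit`` takes ``X`` with shape
    (n_samples, n_features); it is transposed internally to the
    features x samples orientation of the model.
    """

    def __init__(
        self,
        k_neighbors: int | None = None,
        lam: float = 0.5,
        zscore: bool = True,
        normalize: bool = True,
        mu_init: float = 1e-2,
        mu_growth: float = 1.1,
        mu_max: float = 1e10,
        max_iter: int = 500,
        tol: float = 1e-6,
    ):
        self.k_neighbors = k_neighbors
        self.lam = lam
        self.zscore = zscore
        self.normalize = normalize
        self.mu_init = mu_init
        self.mu_growth = mu_growth
        self.mu_max = mu_max
        self.max_iter = max_iter
        self.tol = tol

    def _config(self) -> SolverConfig:
        return SolverConfig(
            lam=self.lam,
            mu_init=self.mu_init,
            mu_growth=self.mu_growth,
            mu_max=self.mu_max,
            max_iter=self.max_iter,
            tol=self.tol,
        )

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_samples, n_features)")
        Xm = X.T  # features x samples
        if self.zscore:
            Xm = zscore_features(Xm)
        if self.normalize:
            Xm = spectral_rescale(Xm)
        n = Xm.shape[1]
        k = self.k_neighbors if self.k_neighbors is not None else default_k_neighbors(n)
        self.support_ = knn_adjacency(Xm, k)
        self.solution_ = solve_lrr(Xm, self.support_, self._config())
        self.representation_ = self.solution_.Z
        self.affinity_ = affinity_from_representation(self.solution_).W
        self.n_iter_ = self.solution_.iterations
        self.converged_ = self.solution_.converged
        return self

    def fit_transform(self, X, y=None) -> np.ndarray:
        """Fit and return the learned sample affinity matrix."""
        return self.fit(X).affinity_
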