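# Methods

## Problem setting

Given m ≥ 2 omics data types measured on the same n samples (each view a
real h_i × n matrix X^i, e.g. expression and copy number), the package
estimates one consensus partition of the samples. The premise is that
heterogeneous samples do not fill one feature space uniformly: groups of
samples occupy different low-dimensional subspaces (different active gene
programs), and each data type may resolve only part of the group structure.
Pairwise-distance methods flatten this union-of-subspaces geometry; the
pipeline below measures similarity by *representation* instead, then fuses
the per-view similarity graphs.

## Stage 1 — locality-constrained low-rank representation (per view)

Each view is modelled as X = XZ + E: every sample is an affine combination
of other samples, with

    min_{Z,E}  ||Z||_* + λ ||E||_{2,1}
    s.t.  X = XZ + E,   Zᵀ1 = 1,   Z_ij = 0 for (i,j) outside Ω,

where ||Z||_* (nuclear norm) drives Z toward the low-rank, block-diagonal
pattern characteristic of samples drawn from a union of subspaces,
||E||_{2,1} (sum of column norms) absorbs sample-specific outliers, the
column-sum constraint makes the combinations affine, and Ω restricts the
representers of each sample to its K nearest neighbours in Euclidean
distance (self excluded), forcing the representation to be locally
supported. The affinity passed downstream is W = (|Z*| + |Z*ᵀ|)/2.

### Solver

The problem is split (J = Z) and solved by a linearized ADMM with adaptive
penalty (LADMAP). Per iteration, with penalty μ:

1. J ← SVT(Z + Y₃/μ, 1/μ) — singular-value soft-thresholding, the proximal
   operator of the nuclear norm;
2. E ← column-shrink(X − XZ + Y₁/μ, λ/μ) — each column scaled by
   max(0, 1 − τ/||·||₂), the proximal operator of the l2,1 norm;
3. Z ← Proj_Ω(Z − H/η), a single linearized gradient step on the quadratic
   coupling term, with
   H = −Xᵀ(X − XZ − E + Y₁/μ) − 1(1ᵀ − 1ᵀZ + Y₂/μ) + (Z − J + Y₃/μ) and
   step size η = ||X||₂² + n + 1 (an upper bound on the coupling-term
   curvature: spectral norm of XᵀX + 1·1ᵀ + I);
4. gradient ascent on the three multipliers, then μ ← min(μ_max, ρμ).

Defaults: λ = 0.5, μ₀ = 10⁻², ρ = 1.1, μ_max = 10¹⁰, max_iter = 500,
tol = 10⁻⁶ on the max-norm of the three constraint residuals. K defaults to
10% of n, floored at 3. The Z-subproblem takes exactly one linearized step
per outer iteration; the projection keeps Z exactly zero outside Ω at every
iterate, so support violations are structurally impossible. Non-convergence
within max_iter returns the last iterate with a warning (the affinity may
still be usable downstream); non-finite residuals abort with the iteration
and residual named.

### Preprocessing and conditioning

Two preprocessing steps are on by default and user-overridable. (i)
Per-feature z-scoring within each view, so features on different scales do
not dominate λ. (ii) A global rescale of each view to spectral norm √n.
The rescale deserves a note: a scalar rescale of X is mathematically a
reparametrization of λ (the feasible error E scales with X), so it does not
change the model family — but it changes conditioning decisively. With
z-scored omics-scale views, ||X||₂² is typically two orders of magnitude
larger than n, the step size η is dominated by the reconstruction block,
and the column-sum residual contracts at roughly (1 − n/η) per iteration —
too slowly to meet tol within the iteration budget. At ||X||₂² = n all
three constraint blocks share the same curvature scale and the solver
converges in ~150–250 iterations on the benchmark sizes used here.

## Stage 2 — cross-view graph diffusion

Each per-view affinity is normalized two ways:

- status matrix P (full kernel): P(i,j) = W(i,j) / (2 Σ_{k≠i} W(i,k)) off
  the diagonal, P(i,i) = 1/2 — row-stochastic, half the mass on the sample
  itself, damping scale differences between views;
- local kernel S: row-stochastic restriction of W to each sample's K
  strongest neighbours (ties by ascending index), zero elsewhere.

Diffusion updates all views simultaneously from the previous iterate:

    P^i ← S^i ( Σ_{k≠i} P^k / (m−1) ) (S^i)ᵀ,

i.e. each view passes the average of the *other* views' global similarity
through its own local neighbourhoods. Similarity supported across views is
reinforced; view-specific links decay. After each sweep every P is passed
through the status normalization again: the raw update does not preserve
row sums, and without renormalization the iteration contracts toward zero
off-diagonal mass (the literal update is available via
``renormalize=False`` / ``--no-renormalize`` for comparison). Iteration
stops when the largest elementwise change falls below 10⁻⁶ (default) or
after 30 sweeps; on the benchmark fixtures convergence takes 5–10 sweeps.
The fused network is W# = (Σ_i P^i)/m, symmetrized by averaging with its
transpose so the spectral step sees a symmetric operator. Samples whose
K-neighbourhood carries zero affinity get a zero kernel row and a warning
rather than an error — they can still receive similarity from other views.

## Stage 3 — Ratio-Cut spectral clustering

The fused network is partitioned by the Ratio-Cut relaxation: eigenvectors
of the c smallest eigenvalues of the unnormalized Laplacian L = D − W#,
discretized by k-means (50 restarts, all seeded). For c = 2 the partition
is additionally refined by sweeping every threshold cut along the Fiedler
ordering and keeping whichever candidate has the lower Ratio-Cut objective;
k-means minimizes embedding inertia, which is not always the minimum-cut
discretization on unstructured graphs. Eigenvector signs are fixed
(largest-magnitude entry positive) so results are reproducible and
permutation-equivariant. Labels are integers 1..c.

When the cluster count is not known, ``n_clusters="auto"`` scans a range
and keeps the count maximizing the mean silhouette width of the partition
on W#, ties to the smaller count. Silhouette on a similarity network needs
a dissimilarity; the convention here is d = 1 − W/max(W) with zero
diagonal. Members of singleton clusters contribute silhouette 0.

## Synthetic benchmark generator

The generator plants C clusters of equal size (defaults: 3 × 30 samples,
two views with 500 and 300 features) and gives each view a *merge plan*:
the cluster pairs that view cannot distinguish. The default plan (view 1
merges {2,3}, view 2 merges {1,2}) makes every single view blind to one
boundary while the combination resolves all three clusters — the regime
fusion exists for. A plan that leaves some cluster pair merged in every
view is rejected as infeasible.

Signals are low-rank: cluster loadings in a small number of latent
dimensions (4 per cluster), embedded through random orthonormal bases into
the view's feature space. Two heterogeneity regimes:

- ``single-subspace``: each effective group is an isotropic Gaussian cloud
  (unit variance, centre at distance 3 from the origin) in one affine
  subspace; merged clusters share the cloud and are *truly*
  indistinguishable in that view, at every level of description.
- ``multi-manifold`` (default): each cluster lies on its own curved 1-D
  manifold — an arc (radius 1.5, span 1.2π) with a drift of ±2 along a
  cluster-specific direction, small isotropic jitter (σ = 0.05). Clusters a
  view merges share the offset + arc plane but drift along different
  orthogonal directions, so their manifolds cross where the drift vanishes:
  Euclidean neighbourhoods mix the pair there and pairwise-kernel methods
  lose that boundary, while each manifold remains a distinct 4-dimensional
  subspace that representation-based affinity resolves.

Noise is additive Gaussian with σ = noise_frac × the elementwise standard
deviation of the clean signal; the study conditions are noise_frac ∈
{0, 0.10, 0.30}. Everything is drawn from one seeded generator, so a spec
(including its seed) reproduces the dataset bitwise.

The single-view reference (``single_view_ceiling``) scores spectral
clustering of one view's raw Gaussian-kernel similarity against the truth.
The kernel bandwidth is the local-scaling heuristic — median over samples
of the mean distance to the 10%-of-n nearest neighbours — because a global
median-distance bandwidth leaves the kernel nearly flat on these geometries
and the comparison would be against a strawman.

What the generator does *not* emulate: real platform feature distributions
(heavy tails, count structure, feature correlation blocks), missing values,
batch effects, or unequal cluster sizes. Passing tests therefore show that
the pipeline recovers planted union-of-subspace structure under additive
noise at realistic sample counts — not that it is robust to every artefact
of real omics data.

## Numerical choices and degenerate inputs

- KNN and top-K ties broken by ascending sample index (deterministic under
  duplicated coordinates).
- A sample with no positive off-diagonal affinity makes the status matrix
  undefined; it is reported by name and rejected.
- All-equal similarity matrices make every cluster count equivalent;
  ``select_num_clusters`` warns and returns the smallest candidate.
- The solver is fully deterministic; the only stochastic step in the
  pipeline is k-means, controlled by a single seed.
- Problem sizes in the test and acceptance protocols follow the benchmark
  design: 90 samples per dataset, 50 seeds per noise level for the accuracy
  protocol, 20 seeds per setting for the parameter-robustness protocol
  (K ∈ {5,8,11,14} at λ = 0.5; λ ∈ {0.1,0.3,0.5,0.8,1.0} at K = 8, one
  parameter varied at a time).

## Known limitations

- The per-view solve is O(n²h + n³) per iteration; the implementation is
  dense and aimed at cohort sizes of order 10²–10³ samples, not single-cell
  scale.
- Diffusion weighs all views uniformly; there is no view weighting or
  view-quality estimate.
- Binary or categorical data types (mutation status, clinical covariates)
  are out of scope; inputs are assumed continuous.
- In the single-subspace regime, clusters merged within a view are
  indistinguishable there by construction; fusion recovers them only to the
  extent the other views separate them.
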