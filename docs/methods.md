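# Methods

This note documents the models, estimators and numerical choices behind
`velofate`, what the synthetic generators do and do not emulate, and the
design decisions made where several reasonable options existed.

## The directed chain

Each observed cell is a microstate of a discrete-time Markov chain. Two
information sources define the transition probabilities:

- **Manifold topology.** A KNN graph (Euclidean distances over the first
  `L = 30` principal components, `K = 30` neighbors, union-symmetrized)
  restricts transitions to transcriptomically adjacent cells. PCA is
  centered and unscaled by default; a `scale` flag standardizes genes
  first. Similarities on graph edges come from a local-scale exponential
  kernel with smooth-k normalization, symmetrized by the probabilistic
  t-conorm `a + b − ab` (a Gaussian kernel with density-adaptive bandwidth,
  mean-symmetrized, is available as an alternative). Distance ties and
  duplicate cells are handled deterministically; zero distances are floored
  at 1e-300 so the edge survives sparse storage.
- **Velocity direction.** Pearson correlation between a cell's velocity
  vector and each state-change vector measures the cosine of the angle
  between the predicted and the realized expression change. Genes without
  velocity estimates are excluded from the correlation per cell. The
  softmax inverse temperature σ defaults to `1 / median |c|` over all graph
  edges; the estimate is computed once from the plain (deterministic)
  correlations and shared by all uncertainty modes, because re-estimating
  it per mode or per Monte-Carlo draw would make runs incomparable. An
  undefined correlation row (constant velocity vector) falls back to a
  uniform distribution over the neighbors with a warning; a field with no
  directional information anywhere therefore degrades to a similarity-free
  random walk rather than failing, which also makes forward and backward
  chains of a zero field identical, as they should be.

The final chain is `P = (1 − λ) P_v + λ P_s` with λ = 0.2 by default;
λ trades robustness to velocity noise against directional sharpness.
Double density normalization (`Dg⁻¹ A Dg⁻¹`) is available but off by
default.

## Velocity uncertainty

Velocities are noisy estimates, so each `v_i` is modeled as multivariate
normal with diagonal covariance; mean and per-gene variance are the first
two moments of the velocities over the cell's neighborhood *including the
cell itself* (the self-inclusive estimate is defined for singleton
neighborhoods and biases the mean toward the observed vector). Variance
entries below 1e-14 of the second moment are zeroed: they are
catastrophic-cancellation dust, and treating them as real variance would
prevent the zero-variance case from reducing exactly to the deterministic
row.

The expected transition row `E[h(v)]` is approximated to second order:
`h(μ) + ½ Σ_j H_jj Var[v_j]`, with the Hessian diagonals of the
softmax-of-correlation map computed analytically (the derivation chains the
softmax Hessian through the Jacobian and the diagonal second derivatives of
the Pearson map; tests verify agreement with central finite differences to
1e-6 relative). The corrected row can leave the simplex, so negatives are
clipped and the row renormalized. Where the expansion is invalid — mean
velocity near zero with comparable variance, as at attractor tips — the
analytic and sampled expectations genuinely diverge; the sampling mode
(default 1,000 seeded draws, vectorized) is exact in the limit and is the
reference in that regime.

## Coarse-graining

The chain is non-reversible, so invariant subspaces are taken from a sorted
real Schur decomposition rather than an eigendecomposition. The
implementation computes a dense Schur factorization and reorders diagonal
blocks with LAPACK `dtrexc` (selection sort of the leading m blocks by
descending eigenvalue real part, or modulus for cyclic dynamics). This
sequential dense path is the method of choice at the scales this package
targets (N up to a few thousand); no iterative Krylov variant is provided.
2×2 blocks (conjugate pairs) are never split: a request that would cut one
is reported with the two admissible neighboring sizes, and the pipeline
retries with one column more.

Memberships are `χ = Q̃ A` where `Q̃` is the D-orthonormal basis of the
leading subspace with its first column fixed to the constant vector
(uniform weights D by default). The rotation is initialized by an
inner-simplex vertex search — greedily picking the rows of `Q̃` that span
the largest simplex — and optimized by Nelder–Mead over the `(n_s − 1)²`
free entries; after every step the first row and column of `A` are
reconstructed from the positivity and partition-of-unity constraint
equations and the matrix rescaled, so every iterate is feasible. The
optimizer is deterministic given the initial guess; 10,000 function
evaluations are allowed and early stops return the best feasible point with
a warning.

Model selection offers the eigengap heuristic (ties broken toward fewer
states), a crispness scan (`ξ = trace(D̃⁻¹χᵀDχ)/n_s`, computed per
candidate on one shared decomposition truncated per candidate), and a
minChi prefilter (|minChi| ≤ 0.05) followed by the crispness scan. minChi
is evaluated on the *unoptimized* membership from the vertex-search
rotation; the constraint fill would trivially push it to zero.

The projected chain is `P_c = (χᵀDχ)⁻¹(χᵀDPχ)`. Soft overlap makes
small negative entries unavoidable: a weakly metastable macrostate — the
initial state the method is explicitly designed to surface — produces
negatives of order 1e-4 even at the correct number of macrostates. `P_c`
entries below −1e-2 (a percent of probability mass) are treated as a
modeling error and raise; smaller negatives are clipped with a warning and
rows renormalized.

## State classification

Terminal states: `SI = diag(P_c) ≥ ε_SI` with `ε_SI = 0.96`. A manual
override can promote a known terminal population whose SI falls below the
threshold; no heuristic replaces that judgment. Initial states: smallest
entries of `π_c = χᵀπ` among non-terminal, non-outlier macrostates (one
by default; ties broken by index with a warning). Terminal macrostates are
excluded from the initial candidates so a single-macrostate system cannot
be both. `π` is the left unit eigenvector of `P` (dense for N ≤ 2,000,
Arnoldi beyond), validated by `‖πᵀP − πᵀ‖₁ ≤ 1e-8`. Reducible chains
(disconnected graphs) are reported with their components; macrostates
living entirely outside the main component with no coarse in-/out-flow are
flagged as outliers and excluded, and `π` is computed on the main
component when it is closed. For sources too unstable to appear as forward
macrostates, the chain is reversed (velocities negated) and terminal states
of the backward chain are reported as initial states of the forward one.

## Fate probabilities

For each selected macrostate the `f = 30` cells with largest membership
form its terminal index set; a cell claimed by two sets goes to the one
with the larger membership and the loser backfills, keeping the sets
disjoint. Rows of target cells are replaced by self-loops; `(I − Q)A = S`
is solved with a shared sparse LU factorization (a per-column GMRES path
with ILU preconditioning and 1e-8 relative residual is available and
agrees to 1e-6). Right-hand sides are aggregated per lineage *before* the
solve — the map is linear, so this is exact and cheaper than solving per
recurrent cell. Negatives beyond −1e-10 or row sums far from one indicate
unreachable targets and raise with the offending cells. A vectorized,
seeded random-walk estimator serves as an independent oracle in tests.

## Downstream analyses

- **Circular embedding**: lineages at evenly spaced angles, cells at the
  fate-weighted average of the vertices. The circular order maximizes
  summed cosine similarity of adjacent fate columns — exhaustive over
  circular permutations (first lineage fixed, reflections deduplicated) up
  to 8 lineages, greedy insertion beyond.
- **Priming**: entropy `−Σ F ln F` and `KL(F_i ‖ F̄)` with natural
  logarithms and `0 ln 0 := 0`; an infinite divergence is reported as such
  when the mean fate has an empty lineage.
- **Drivers**: per-gene Pearson correlation with a fate column, optionally
  restricted to named clusters (≥ 3 cells); zero-variance genes are
  flagged undefined and ranked last.
- **Trends**: weighted penalized regression on a cubic B-spline basis, 8
  interior knots at weighted pseudotime quantiles, ridge penalty on second
  differences selected by GCV over a fixed log-spaced grid that includes 0
  (so exactly representable trends — linear included — are reproduced
  without penalty bias). Only cells with positive weight enter the fit;
  fate weights below 0.01 may be clipped up to that value so sparsely
  populated lineages still constrain early pseudotime. Predictions are made
  at 200 equally spaced points spanning the contributing cells' range. The
  uncertainty band is `σ̂ · sqrt(1 + 1/n + (τ_p − τ̄)²/Σ(τ_j − τ̄)²)`
  with `σ̂² = Σ r_j²/(n − 2)`; `n` is the number of *test points*, as
  this estimator is conventionally printed in the field's software, with a
  flag switching to the number of fitted cells. The fit commutes with
  affine rescaling of the response to 1e-8.
- **Trend clustering**: per-gene z-transform of the smoothed trends, PCA
  (50 components), KNN graph, seeded Leiden partition with a Louvain-style
  resolution parameter (0.2 default); per-cluster pointwise mean and s.d.
- **Smoothing**: optional neighbor-average imputation (a row-stochastic
  smoothing operator applied a chosen number of steps) for users without an
  externally imputed matrix.

## Synthetic generators

All generators are pure functions of parameters and seed.

- **Planted chains**: block-uniform rows with mass 1 − ε and a leak ε
  routed by a block topology (line, cycle, all, or a doubly stochastic
  uniform variant whose stationary block masses equal the block-size
  fractions). Ground-truth labels are returned.
- **Branching fields**: latent 3-D cubic Bézier curves sharing their first
  two control points (common root and tangent), fanning out at evenly
  spread angles, embedded into gene space by a seeded orthonormal map.
  Velocities are exact curve derivatives under the speed profile
  `3 t (1 − t)²`: zero at the progenitor pool (a quasi-steady repelling
  fixed point, as in real differentiation kinetics where progenitors linger
  before committing) and zero again at the attractors. Defaults: 1,000
  cells, 20 genes, 2 branches, Gaussian noise with σ = 0.1 on both
  expression and velocity against a curve scale of order 4 — a
  signal-to-noise ratio typical of imputed log-expression data.
- **Trend families**: genes drawn from named smooth templates (linear,
  sigmoid, transient peak) with per-gene amplitude jitter and Gaussian
  noise.

What the generators do **not** emulate: count-level (negative binomial)
noise, splicing kinetics, batch effects, doublets, or cell-type-specific
velocity biases. Passing tests on these fixtures therefore demonstrates
correctness of the chain construction, coarse-graining and absorption
machinery under the model's own assumptions — not robustness to the full
noise structure of real single-cell data.

## Problem sizes and determinism

The shipped tests and the reproduction script use 200–1,000 cells,
30–300-state chains, and 10 simulation seeds; these sizes give stable
pass/fail behaviour at interactive runtimes while exercising every code
path, including the dense Schur reordering at N = 1,000. Deterministic
modes are bit-reproducible; sampling-based paths (Monte-Carlo kernel mode,
random-walk oracle, Leiden) are reproducible under a fixed seed.

## Known limitations

- The dense Schur path is cubic in cell number; beyond ~5,000 cells a
  partial iterative decomposition would be needed.
- Velocity covariance is diagonal; correlated gene noise is not propagated.
- The second-order expectation is unreliable where mean velocity vanishes
  (trajectory endpoints); use the sampling mode there.
- The Nelder–Mead rotation optimization is local; for heavily overlapping
  macrostates different initializations could reach different optima
  (the inner-simplex start makes this rare in practice).
- Terminal-state calling depends on the single threshold ε_SI; no
  automatic tuning is attempted.
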