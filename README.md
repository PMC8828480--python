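# velofate

Velocity-directed Markov-chain fate mapping for single-cell transcriptomics.

Given a cell-by-gene expression matrix `X ∈ R^{N×G}` (normalized, log-scaled
or imputed) and a matching RNA-velocity matrix `V ∈ R^{N×G}` (per-cell, per-gene
time derivatives of expression), `velofate` answers the questions a
developmental biologist asks of a differentiation dataset: where do cells
start, where do they end up, how likely is each individual cell to adopt each
fate, and which genes track each fate decision.

## Method

**1. A directed Markov chain over cells.** A symmetrized KNN graph in PCA
space (K = 30 neighbors, L = 30 PCs by default) restricts transitions to the
phenotypic manifold. For cell *i* with velocity `v_i`, Pearson correlations
`c_ik` between `v_i` and the state-change vectors `s_ik = x_k − x_i` are
mapped through a softmax

    p_ik = exp(σ c_ik) / Σ_l exp(σ c_il),      σ = 1 / median |c_ik|,

giving the velocity kernel `P_v`. It is blended with the similarity kernel
`P_s` (row-normalized graph adjacency) as `P = (1 − λ) P_v + λ P_s`
(λ = 0.2). Velocity noise is handled by modeling `v_i ~ N(μ_i, Σ_i)` with
moments estimated from the neighborhood and propagating it into the expected
transition row with a second-order Taylor expansion using analytic Hessian
diagonals of the softmax-of-correlation map (mode `stochastic`, the
default), or by Monte-Carlo sampling (mode `sampling`).

**2. Coarse-graining into macrostates (GPCCA).** The leading invariant
subspace of the non-reversible chain is obtained from a sorted real Schur
decomposition; memberships `χ = Q̃ A` are optimized over rotations `A` to
minimize `f(A) = n_s − trace(D̃⁻¹ χᵀ D χ)` subject to `χ ≥ 0`,
`χ 1 = 1` (Nelder–Mead with constraint projection). The coarse chain is
`P_c = (χᵀ D χ)⁻¹ (χᵀ D P χ)`. Terminal states have stability index
`SI = diag(P_c) ≥ 0.96`; initial states have the smallest coarse-grained
stationary mass `π_c = χᵀ π`; reversing the velocity arrows recovers
unstable initial states as terminal states of the backward chain.

**3. Fate probabilities by absorption.** The `f = 30` cells most confidently
assigned to each terminal macrostate are made absorbing and `(I − Q) A = S`
is solved sparsely; summing columns per target set gives the fate matrix
`F ∈ R^{N×n_t}`. Downstream: circular fate embeddings, priming scores
(entropy and KL divergence from the mean fate), driver-gene ranking by
correlation with fate columns, and fate-weighted cubic-spline expression
trends along pseudotime with a residual-s.d. band.

## Worked example

```python
import numpy as np
import velofate as vf

# a simulated 1,000-cell bifurcating trajectory with known ground truth
field = vf.simulate_branching_field(n_cells=1000, n_genes=20,
                                    n_branches=2, seed=0)
cfg = vf.RunConfig(n_macrostates=3, seed=0)
result = vf.run_pipeline(field.expr, field.vel, cfg)

print("sigma (auto):", round(result.report["sigma"], 3))
print("stability indices:", np.round(result.classification.stability_index, 3))
print("terminal:", sorted(result.classification.terminal))
print("initial:", sorted(result.classification.initial))
print("mean fate of early cells:",
      np.round(result.fate.probs[field.true_time < 0.2].mean(axis=0), 3))
```

prints

```
sigma (auto): 4.597
stability indices: [0.786 1.    1.   ]
terminal: [1, 2]
initial: [0]
mean fate of early cells: [0.545 0.455]
```

The two branch attractors come out as terminal macrostates with
self-transition probability 1.0; the progenitor pool (stability 0.79, the
smallest coarse stationary mass, here 2.9 × 10⁻⁴) is called initial; and
cells before the bifurcation are near-uncommitted, with fate probabilities
close to (0.5, 0.5) toward the two lineages. Their fate entropy is near
ln 2 ≈ 0.69 and drops to 0 at the branch tips.

The same pipeline is available from the shell:

```bash
velofate simulate --n-cells 1000 --seed 0 --out-dir data/
velofate run --expression data/expression.mtx --velocity data/velocity.mtx \
             --n-macrostates 3 --seed 0 --out-dir results/
```

which writes the transition matrix (Matrix Market), memberships, coarse
transition matrix, state classification, fate probabilities (TSV) and a JSON
run report. Subcommands `kernel`, `macrostates`, `states`, `fate`,
`drivers` and `trends` expose the individual stages.

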