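# Methods

## Model

`tgplvm` implements a Gaussian process latent variable model with
Student-t observation noise (tGPLVM) for low-dimensional embedding of
cell-by-gene expression matrices. With `Y ∈ R^{N×P}` (N cells, P genes)
and latent positions `X ∈ R^{N×Q}`:

- latent prior: `x_n ~ N_Q(0, I)`;
- per-gene noiseless profiles: `f_p(X) ~ N(0, K_NN)` under a composite
  kernel `k(x, x') = Σ_m k_m(x, x')`;
- observations: `y_np ~ StudentT(f_np, ν, τ²_p)` with fixed degrees of
  freedom (default ν = 4, configurable over [1, 10]) and a per-gene noise
  scale `τ²_p`, or `y_np ~ N(f_np, τ²_p)` for the normal-error variant.

The kernel sum combines a squared-exponential component with Matérn 1/2,
3/2 and 5/2 components (presets: `full`, `m12` = SE + Matérn 1/2, `rbf` =
SE only), each with its own scale `σ²_m` and ARD length scales `ℓ_{m,q}`.
Length scales are per latent dimension, so an irrelevant dimension is
expressed by a large `ℓ`; no automatic dimension pruning is performed, but
`FitResult.ard_inverse_length_scales()` reports the relevances for manual
inspection.

### Distance form inside the kernels

Two weighted latent distances are supported:

- `l1`: `r_m = Σ_q |x_q − x'_q| / ℓ_{m,q}`;
- `l2`: `r_m = sqrt(Σ_q (x_q − x'_q)² / ℓ²_{m,q})` (conventional).

The `l1` form is the default in the kernel module, but it is **not a valid
positive-definite kernel construction for Q > 1** when plugged into the
SE/Matérn 3/2/5/2 shapes (the squared weighted-L1 distance is not
negative definite; empirically the minimum Gram eigenvalue can reach about
−2% of the total kernel variance). Self-Gram matrices therefore carry a
jitter of `1e-6 × Σ_m σ²_m`, escalated tenfold on Cholesky failure up to
`1e-2 × Σ_m σ²_m` before raising. During optimization with learned length
scales the L1 form exceeds even that cap within a few dozen gradient
steps, so **model fitting defaults to `l2`**; `distance="l1"` remains
available for experimentation.

## Inference

Black-box stochastic variational inference with the reparameterization
trick, on a small reverse-mode automatic-differentiation tape
(`tgplvm._autodiff`, finite-difference checked). The variational family is
the standard sparse-GP construction:

- `q(x_{n,q}) = N(μ_{n,q}, s²_{n,q})`, fully factorized with free means
  and scales;
- shared inducing inputs `Z ∈ R^{M×Q}` (default M = 100, capped at N);
- whitened per-gene inducing outputs `v_p ~ N(m_p, S)` with per-gene means
  and a single shared Cholesky-parameterized covariance `S = C Cᵀ`.

The per-entry marginal of `f_np` under `q` is Gaussian with mean
`a_nᵀ m_p` and variance `k(x_n,x_n) − a_nᵀ a_n + a_nᵀ S a_n`
(`a_n = L_mm^{-1} k_{m,n}`), which is all the factorized likelihood needs;
the ELBO is

`Σ_np E_q[log p(y_np | f_np)] − KL(q(X) ‖ N(0,I)) − Σ_p KL(q(v_p) ‖ N(0,I))`,

estimated with one reparameterized draw per step by default. The Student-t
log-density is evaluated directly on the draws (no scale-mixture
augmentation), so switching the error model costs nothing. Kernel
hyperparameters, `τ²_p` and `Z` are point-estimated by the same Adam loop
(default learning rate 0.01); positivity is enforced by optimizing logs.

Minibatching: cells are sampled uniformly without replacement each epoch
(batch `min(2500, N)`); genes are sampled by randomized-order systematic
probability-proportional-to-size sampling with selection weight equal to
the fraction of cells expressing the gene (batch `min(250, P)`). The
systematic design has *exact* inclusion probabilities (proportional
shares iteratively capped at 1), so weighting each sampled gene's
likelihood and KL terms by the inverse inclusion probability makes the
stochastic ELBO exactly unbiased; this is verified empirically in the
test suite.

Initialization: PCA scores standardized to unit column variance (latent
scales start at 0.1) or standard-normal random (scales start at 1.0);
inducing inputs start at a random subset of the initial means; `τ²_p`
starts at half the gene's variance; kernel scales split the mean gene
variance equally across components with unit length scales. Fits are
bitwise reproducible given the seed in single-threaded execution. A
non-finite ELBO or an unrecoverable Cholesky failure aborts the loop with
the last finite state and a warning rather than raising.

## Simulation benchmark

`simulate_dataset` draws a 2-D branching trajectory: a unit-length trunk
from the origin in a random direction and (by default) two unit-length
child branches leaving the trunk endpoint at random angles of 30-150° on
alternating sides (a Y-shaped manifold); points sit at sorted uniform
positions along their segment with isotropic Gaussian wiggle of sd 2% of
the segment length. The latent points are projected to P = 10 dimensions
by independent draws from an SE-kernel GP (variance 1, length scale 0.25 ×
trunk length). Noise is either

- Gaussian: `N(0, level × max(F))` — the *variance* is the stated fraction
  of the maximum noiseless value, with level on the grid 0.1, …, 1.0; or
- zero-centered gamma: `Gamma(shape = level × max(F), scale = 1)` minus its
  mean `shape × scale`, i.e. right-skewed noise with zero mean.

The generator emulates the benchmark's branching geometry and noise
families, not real scRNA-seq counts: emissions are real-valued, there is
no dropout, no count noise, no library-size variation. Passing benchmarks
therefore demonstrate manifold recovery under the stated noise families,
not performance on droplet data.

## Evaluation

- **W2 manifold recovery**: for each cell, the discrete optimal-transport
  distance between its row of the row-normalized Euclidean distance matrix
  of the estimate and of the truth. The ground cost between support cells
  j,k is the true pairwise distance normalized by the mean off-diagonal
  true distance (making the metric invariant to similarity transforms of
  either embedding — the raw cost would scale with the truth's units);
  squared under the default W2 convention (minimize expected squared cost,
  return the root; `order=1` gives W1). Solvers: exact per-row linear
  programs (HiGHS) for N ≤ 64, or a batched ε-annealed Sinkhorn solver
  (ε = 0.01 on the normalized squared cost, ~1-2% upward bias, shared
  across all compared embeddings) for larger N.
- **Clustering**: k-means (k = number of distinct labels, k-means++ with
  seed `base_seed + repeat`, 300-iteration cap, 10 repeats) scored by NMI
  (geometric-mean normalization) and adjusted Rand score. Degenerate NMI
  convention: two single-cluster partitions score 1, a single-cluster vs a
  multi-cluster partition scores 0.
- **MST trajectories**: Kruskal on the complete Euclidean graph with
  deterministic (weight, i, j) tie-breaking.
- **Latent-gene correlations**: Pearson r between each latent dimension's
  posterior means and each gene; constant genes yield NaN, never 0.

## Desk-scale study conditions

The noise-robustness sweeps (`tgplvm benchmark`, `scripts/acceptance.py`,
and the acceptance tests) run at N = 150 cells, P = 10 dimensions, Q = 2,
with 16 inducing points, a fixed budget of 300 full-batch passes, and 25
replicate seeds per grid cell; each replicate simulates one dataset and
fits both error models on it (a paired design). The learning rate (0.1)
is the largest at which both error models remain stable on low-noise data
under this budget: at 0.2 the normal-error fits degrade even at the lowest
noise level, while at 0.1 the two error models recover the manifold
equally well there. Reported W2 values use the Sinkhorn solver, whose
entropic bias is common to all compared fits.

## Known limitations

- The variational family is a documented stand-in for the original
  construction, whose exact form is not public; equivalence is not
  claimed, and absolute W2 values depend on the optimization regime.
- The Student-t ELBO uses single-sample reparameterized gradients; traces
  are noisy and fixed budgets, not convergence criteria, define a run.
- Count-valued emissions (Poisson/NB/multinomial), dropout simulation,
  batch correction and imputation are out of scope.
- GPU execution and learned ν are not supported.
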