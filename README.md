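# tgplvm

Robust nonlinear dimension reduction for single-cell RNA-seq count
matrices with a **Student-t Gaussian process latent variable model
(tGPLVM)**.

Single-cell expression matrices are sparse, heavy-tailed and full of
technical and biological outliers. `tgplvm` embeds cells into a
low-dimensional nonlinear latent space while staying robust to that
noise: expression of each gene is modeled as a Gaussian-process function
of latent cell positions, and the observation error is Student-t rather
than Gaussian:

    x_n  ~ N_Q(0, I)                          latent cell positions
    f_p  ~ GP(0, k)     k = k_SE + k_Mat1/2 + k_Mat3/2 + k_Mat5/2
    y_np ~ StudentT(f_np, nu, tau2_p)         nu = 4 by default

Each kernel component has per-dimension ARD length scales learned from
the data, so the composite kernel adapts from non-smooth (Matérn 1/2) to
smooth (SE) geometry. Inference is stochastic variational (sparse GP
with inducing points, minibatches of cells and of genes sampled by
expression rate), so fits scale far beyond what an exact GPLVM allows.

The package is aimed at computational biologists who want embeddings with
calibrated per-cell uncertainty from *unfiltered* counts, plus the
downstream primitives the embedding feeds: k-means cell-type scoring
(NMI/ARS), minimum-spanning-tree trajectory scaffolds, and latent–gene
correlation scans. A built-in simulator reproduces the branching-manifold
benchmark used to validate the robustness claim.

## Worked example

```python
import numpy as np
from tgplvm import (ModelConfig, fit, simulate_dataset,
                    w2_manifold_distance, kmeans_cluster_scores)

ds = simulate_dataset(n=150, p=10, noise_model="gaussian",
                      noise_level=0.1, seed=0)
result = fit(ds.observed, ModelConfig(q=2, n_inducing=16, epochs=300,
                                      learning_rate=0.1, seed=1))

w2 = w2_manifold_distance(result.posterior_means, ds.truth.latent)
w2_rand = w2_manifold_distance(
    np.random.default_rng(2).standard_normal((150, 2)), ds.truth.latent)
nmi, _, ars, _ = kmeans_cluster_scores(result.posterior_means,
                                       ds.truth.branch_label)
print(f"W2 fitted {w2:.3f} vs random {w2_rand:.3f}; NMI {nmi:.2f}, ARS {ars:.2f}")
```

Output (`examples/02_fit_and_evaluate.py`):

```
ELBO: -4016 (start) -> -1937 (end)
W2 manifold distance: fitted 0.303 vs random embedding 0.421
branch recovery: NMI 0.34+-0.04, ARS 0.31+-0.05
mean posterior variance of latent positions: 0.067
```

The fitted embedding's Wasserstein-2 distance to the true branching
manifold (0.303) is far below a random embedding's (0.421), i.e. the
relative cell geometry is recovered. The k-means branch NMI is modest by
construction: the three branches are contiguous segments of one connected
Y-shaped manifold, so even the ground-truth coordinates score about 0.6.
See `examples/` for simulation, IO, and noise-robustness walkthroughs,
and `docs/methods.md` for the model, inference and evaluation details.

## Command line

```bash
tgplvm simulate --n 150 --p 10 --noise-model gamma --level 0.5 --seed 7 --out-dir sim/
tgplvm fit --counts counts.tsv --q 2 --log-base 10 --out-dir fit/
tgplvm evaluate --embedding fit/posterior_means.tsv --labels labels.tsv --mst --out report.json
tgplvm benchmark --levels 0.1,0.5,1.0 --seeds 5 --out bench.tsv
```

Sparse 10x-style input: `--mtx matrix.mtx --features features.tsv
--barcodes barcodes.tsv` (genes x cells on disk, transposed on read;
`.gz` transparently supported). All randomness is governed by `--seed`;
outputs are byte-stable in single-threaded runs.

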