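"""Simulate the branching-manifold benchmark and describe what it contains.

A 2-D branching trajectory (unit trunk from the origin, two children
diverging at the fork) is projected to 10 observed dimensions by an
SE-kernel Gaussian process and corrupted with zero-mean Gaussian noise
whose variance is 10% of the maximum noiseless value.
"""

import numpy as np

from tgplvm import simulate_dataset

ds = simulate_dataset(n=150, p=10, noise_model="gaussian", noise_level=0.1, seed=0)

print(f"latent truth: {ds.truth.latent.shape}, branches {np.bincount(ds.truth.branch_label)}")
print(f"noiseless projection: {ds.noiseless.shape}, max value {ds.noiseless.max():.3f}")
noise = ds.observed - ds.noiseless
print(
    f"noise: sd {noise.std():.3f} "
    f"(target sqrt(0.1 x max) = {np.sqrt(0.1 * ds.noiseless.max()):.3f})"
)
# The branch labels and pseudotime let downstream scripts score clustering
# and trajectory recovery against a known ground truth.
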