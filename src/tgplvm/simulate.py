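"""Synthetic branching-manifold benchmark data.

The generative benchmark draws a two-dimensional branching trajectory (a
trunk leaving the origin plus child branches diverging from its endpoint),
projects it to ``P`` observed dimensions with independent draws from an
SE-kernel Gaussian process over the latent coordinates, and corrupts the
projection with either zero-mean Gaussian noise (variance expressed as a
fraction of the maximum noiseless value) or zero-centered gamma noise
(scale 1, shape a fraction of the maximum noiseless value).

Defaults: three branches (one trunk, two children), unit-length segments,
2% isotropic wiggle, SE variance 1 and length scale 0.25 x trunk length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kernels import GramMatrix, KernelParams, composite_gram, jittered_cholesky

__all__ = [
    "BranchingTruth",
    "SimulatedDataset",
    "simulate_branching_latent",
    "gp_project",
    "add_noise",
    "simulate_dataset",
]

NOISE_MODELS = ("gaussian", "gamma")


@dataclass
class BranchingTruth:
    """Ground-truth latent geometry of a simulated branching trajectory."""

    latent: np.ndarray  # N x 2
    branch_label: np.ndarray  # N ints, 0 = trunk
    pseudotime: np.ndarray  # N reals in [0, 1]
    seed: int

    @property
    def n(self) -> int:
        return self.latent.shape[0]


@dataclass
class SimulatedDataset:
    """Truth, noiseless GP projection and noisy observations."""

    truth: BranchingTruth
    noiseless: np.ndarray  # N x P
    observed: np.ndarray  # N x P
    noise_model: str
    noise_level: float
    seed: int


def simulate_branching_latent(n: int, n_branches: int = 3, seed: int = 0) -> BranchingTruth:
    """Draw a 2-D branching trajectory.

    A unit-length trunk leaves the origin along a random direction;
    ``n_branches - 1`` unit-length children diverge from the trunk endpoint
    at random angles between 30 and 150 degrees (random side). Points sit
    at sorted uniform pseudotimes along their segment with isotropic
    Gaussian wiggle of sd 2% of segment length.
    """
    if n_branches < 2:
        raise ValueError("need at least 2 branches (trunk + child)")
    if n < 2 * n_branches:
        raise ValueError(f"n={n} too small for {n_branches} branches (need >= {2 * n_branches})")
    rng = np.random.default_rng(seed)
    counts = np.full(n_branches, n // n_branches)
    counts[: n % n_branches] += 1

    theta = rng.uniform(0.0, 2 * np.pi)
    trunk_dir = np.array([np.cos(theta), np.sin(theta)])
    fork = trunk_dir.copy()  # trunk endpoint (unit length)

    coords, labels, ptime = [], [], []
    for b in range(n_branches):
        t = np.sort(rng.uniform(0.0, 1.0, counts[b]))
        if b == 0:
            base, direction = np.zeros(2), trunk_dir
            pt = 0.5 * t
        else:
            # children alternate sides of the trunk so the manifold is
            # Y-shaped rather than collapsing onto one flank
            side = 1.0 if b % 2 else -1.0
            offset = rng.uniform(np.deg2rad(30.0), np.deg2rad(150.0)) * side
            ang = theta + offset
            base, direction = fork, np.array([np.cos(ang), np.sin(ang)])
            pt = 0.5 + 0.5 * t
        xy = base + t[:, None] * direction
        xy = xy + rng.normal(scale=0.02, size=xy.shape)  # 2% of unit segment length
        coords.append(xy)
        labels.append(np.full(counts[b], b))
        ptime.append(pt)

    return BranchingTruth(
        latent=np.vstack(coords),
        branch_label=np.concatenate(labels),
        pseudotime=np.concatenate(ptime),
        seed=seed,
    )


def gp_project(
    truth: BranchingTruth,
    p: int = 10,
    length_scale: float = 0.25,
    variance: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Project latent coordinates to ``p`` dimensions with an SE-kernel GP.

    Each output column is an independent draw from N(0, K) where K is the
    (jittered) SE Gram matrix of the latent coordinates with the given
    length scale (default 0.25 x the unit trunk length) and variance.
    """
    if p < 1:
        raise ValueError("p must be >= 1")
    params = KernelParams(
        variances={"se": variance}, length_scales={"se": np.full(2, length_scale)}
    )
    gram: GramMatrix = composite_gram(truth.latent, params=params, metric="l2")
    L, _ = jittered_cholesky(gram.values, params.total_variance)
    rng = np.random.default_rng(seed)
    return L @ rng.standard_normal((truth.n, p))


def add_noise(F: np.ndarray, model: str, level: float, seed: int = 0) -> np.ndarray:
    """Corrupt a noiseless matrix with Gaussian or zero-centered gamma noise.

    ``gaussian``: adds N(0, level * max(F)) noise (the *variance* is the
    stated fraction of the maximum noiseless value).  ``gamma``: adds
    Gamma(shape = level * max(F), scale = 1) noise minus its mean
    (shape * scale), so the noise is zero-centered but right-skewed.
    """
    F = np.asarray(F, dtype=float)
    if not np.isfinite(F).all():
        raise ValueError("noiseless matrix contains NaN or inf")
    if not 0.0 < level <= 1.0:
        raise ValueError(f"noise level must be in (0, 1], got {level}")
    fmax = F.max()
    if fmax <= 0:
        raise ValueError("max of noiseless data is non-positive; noise scale undefined")
    rng = np.random.default_rng(seed)
    if model == "gaussian":
        return F + rng.normal(scale=np.sqrt(level * fmax), size=F.shape)
    if model == "gamma":
        shape = level * fmax
        return F + rng.gamma(shape=shape, scale=1.0, size=F.shape) - shape
    raise ValueError(f"unknown noise model {model!r}; expected one of {NOISE_MODELS}")


def simulate_dataset(
    n: int = 150,
    p: int = 10,
    n_branches: int = 3,
    noise_model: str = "gaussian",
    noise_level: float = 0.1,
    seed: int = 0,
) -> SimulatedDataset:
    """End-to-end benchmark draw: branching truth -> GP projection -> noise.

    Sub-seeds for the three stages are spawned deterministically from
    ``seed``, so the full triple is reproducible from ``(n, p, seed)``.
    """
    ss = np.random.SeedSequence(seed)
    s_truth, s_proj, s_noise = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(3))
    truth = simulate_branching_latent(n, n_branches=n_branches, seed=s_truth)
    F = gp_project(truth, p=p, seed=s_proj)
    Y = add_noise(F, model=noise_model, level=noise_level, seed=s_noise)
    return SimulatedDataset(
        truth=truth,
        noiseless=F,
        observed=Y,
        noise_model=noise_model,
        noise_level=noise_level,
        seed=seed,
    )
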