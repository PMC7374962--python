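"""Composite ARD kernels for the tGPLVM.

The covariance over latent space is a sum of up to four components — a
squared-exponential (SE/RBF) kernel and Matern kernels with smoothness 1/2,
3/2 and 5/2 — each with its own scale ``sigma^2_m`` and one ARD length scale
per latent dimension ``ell_{m,q}``:

    r_m        = sum_q |x_q - x'_q| / ell_{m,q}          (default, "l1")
    k_SE       = sigma^2 exp(-r^2 / 2)
    k_Mat1/2   = sigma^2 exp(-r)
    k_Mat3/2   = sigma^2 (1 + sqrt(3) r) exp(-sqrt(3) r)
    k_Mat5/2   = sigma^2 (1 + sqrt(5) r + 5/3 r^2) exp(-sqrt(5) r)

The length-scale-weighted distance defaults to the L1 form above; the
conventional weighted L2 form ``sqrt(sum_q (x_q - x'_q)^2 / ell^2_{m,q})``
is available via ``metric="l2"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "COMPONENTS",
    "PRESETS",
    "KernelParams",
    "GramMatrix",
    "scaled_distance",
    "kernel_component",
    "composite_gram",
    "jittered_cholesky",
]

SE = "se"
MAT12 = "mat12"
MAT32 = "mat32"
MAT52 = "mat52"
COMPONENTS = (SE, MAT12, MAT32, MAT52)

#: Kernel ablation presets: full composite, SE + Matern 1/2, or SE only.
PRESETS: dict[str, tuple[str, ...]] = {
    "full": (SE, MAT12, MAT32, MAT52),
    "m12": (SE, MAT12),
    "rbf": (SE,),
}

SQRT3 = np.sqrt(3.0)
SQRT5 = np.sqrt(5.0)


class ParameterError(ValueError):
    """Invalid kernel or model parameter."""


@dataclass
class KernelParams:
    """Scales and ARD length scales of the active kernel components.

    Parameters
    ----------
    variances
        Mapping from component name to ``sigma^2_m > 0``.
    length_scales
        Mapping from component name to a length-Q positive array
        ``ell_{m,q}``.
    """

    variances: Mapping[str, float]
    length_scales: Mapping[str, np.ndarray]

    def __post_init__(self):
        self.variances = {k: float(v) for k, v in self.variances.items()}
        self.length_scales = {
            k: np.atleast_1d(np.asarray(v, dtype=float))
            for k, v in self.length_scales.items()
        }
        if set(self.variances) != set(self.length_scales):
            raise ParameterError("variances and length_scales name different components")
        for name in self.variances:
            if name not in COMPONENTS:
                raise ParameterError(f"unknown kernel component {name!r}")
            if not self.variances[name] > 0:
                raise ParameterError(f"variance of {name!r} must be positive")
            if not np.all(self.length_scales[name] > 0):
                raise ParameterError(f"length scales of {name!r} must be positive")
        qs = {v.shape[0] for v in self.length_scales.values()}
        if len(qs) > 1:
            raise ParameterError("components disagree on latent dimensionality Q")

    @property
    def active_components(self) -> tuple[str, ...]:
        return tuple(c for c in COMPONENTS if c in self.variances)

    @property
    def q(self) -> int:
        return next(iter(self.length_scales.values())).shape[0]

    @property
    def total_variance(self) -> float:
        return float(sum(self.variances.values()))

    @classmethod
    def default(cls, q: int, preset: str = "full") -> "KernelParams":
        """Equal-weight unit-total-variance start with unit length scales."""
        comps = PRESETS[preset]
        return cls(
            variances={c: 1.0 / len(comps) for c in comps},
            length_scales={c: np.ones(q) for c in comps},
        )


@dataclass
class GramMatrix:
    """A kernel covariance matrix with its diagonal jitter."""

    values: np.ndarray
    jitter: float = 0.0

    @property
    def shape(self):
        return self.values.shape


def scaled_distance(x, x_prime, lengths, metric: str = "l1") -> float:
    """Length-scale-weighted latent distance between two points."""
    x = np.asarray(x, dtype=float)
    x_prime = np.asarray(x_prime, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if x.shape != x_prime.shape or x.shape != lengths.shape:
        raise ValueError(
            f"dimension mismatch: x {x.shape}, x' {x_prime.shape}, lengths {lengths.shape}"
        )
    if not np.all(lengths > 0):
        raise ParameterError("length scales must be strictly positive")
    if metric == "l1":
        return float(np.sum(np.abs(x - x_prime) / lengths))
    if metric == "l2":
        return float(np.sqrt(np.sum((x - x_prime) ** 2 / lengths**2)))
    raise ParameterError(f"unknown distance metric {metric!r}")


def kernel_component(r, variance: float, component: str):
    """Evaluate one kernel component at weighted distance(s) ``r``."""
    r = np.asarray(r, dtype=float)
    if not variance > 0:
        raise ParameterError("variance must be positive")
    if component == SE:
        out = variance * np.exp(-0.5 * r**2)
    elif component == MAT12:
        out = variance * np.exp(-r)
    elif component == MAT32:
        out = variance * (1.0 + SQRT3 * r) * np.exp(-SQRT3 * r)
    elif component == MAT52:
        out = variance * (1.0 + SQRT5 * r + (5.0 / 3.0) * r**2) * np.exp(-SQRT5 * r)
    else:
        raise ParameterError(f"unknown kernel component {component!r}")
    return out if out.ndim else float(out)


def _pairwise_scaled(X, X_prime, lengths, metric):
    if metric == "l1":
        return cdist(X / lengths, X_prime / lengths, metric="cityblock")
    if metric == "l2":
        return cdist(X / lengths, X_prime / lengths, metric="euclidean")
    raise ParameterError(f"unknown distance metric {metric!r}")


def composite_gram(
    X,
    X_prime=None,
    params: KernelParams | None = None,
    jitter: float | None = None,
    metric: str = "l1",
) -> GramMatrix:
    """Sum-of-components Gram matrix ``K_ij = sum_m k_m(x_i, x'_j)``.

    Jitter (default ``1e-6 * sum_m sigma^2_m``) is added on the diagonal of
    square self-Gram matrices only.
    """
    X = np.asarray(X, dtype=float)
    self_gram = X_prime is None
    X_prime = X if self_gram else np.asarray(X_prime, dtype=float)
    if X.ndim != 2 or X_prime.ndim != 2 or X.shape[1] != X_prime.shape[1]:
        raise ValueError("latent position arrays must be 2-D with matching Q")
    if not (np.isfinite(X).all() and np.isfinite(X_prime).all()):
        raise ValueError("latent positions contain NaN or inf")
    if params is None:
        params = KernelParams.default(X.shape[1])
    if params.q != X.shape[1]:
        raise ValueError(f"params expect Q={params.q}, data has Q={X.shape[1]}")
    K = np.zeros((X.shape[0], X_prime.shape[0]))
    for comp in params.active_components:
        r = _pairwise_scaled(X, X_prime, params.length_scales[comp], metric)
        K += kernel_component(r, params.variances[comp], comp)
    eff_jitter = 0.0
    if self_gram:
        eff_jitter = 1e-6 * params.total_variance if jitter is None else float(jitter)
        K[np.diag_indices_from(K)] += eff_jitter
    return GramMatrix(values=K, jitter=eff_jitter)


def jittered_cholesky(K: np.ndarray, total_variance: float = 1.0):
    """Cholesky with jitter escalation (x10 per failure up to 1e-2 * variance).

    Returns ``(L, jitter_added)``; raises :class:`numpy.linalg.LinAlgError`
    if the matrix stays indefinite at the jitter cap.
    """
    K = np.asarray(K, dtype=float)
    jitter = 0.0
    step = 1e-6 * total_variance
    cap = 1e-2 * total_variance
    while True:
        try:
            return np.linalg.cholesky(K + jitter * np.eye(K.shape[0])), jitter
        except np.linalg.LinAlgError:
            jitter = step if jitter == 0.0 else jitter * 10.0
            if jitter > cap:
                raise np.linalg.LinAlgError(
                    f"Cholesky failed at maximum jitter {cap:.2e}"
                )
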