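"""The tGPLVM: Student-t observation GPLVM with stochastic variational inference.

Generative model
----------------
Latent positions x_n ~ N_Q(0, I).  Each gene's noiseless expression profile
f_p is a draw from a zero-mean GP over the latent positions under the
composite ARD kernel (see :mod:`tgplvm.kernels`).  Observations are

    y_np | f_np ~ StudentT(f_np, nu, tau^2_p)      (default, nu = 4)
    y_np | f_np ~ N(f_np, tau^2_p)                  (normal-error variant)

with a feature-specific noise scale tau^2_p.

Inference
---------
Black-box stochastic variational inference with the reparameterization
trick.  The variational family is the standard sparse-GP construction:
fully factorized Gaussians over latent positions (free means and scales),
shared inducing inputs Z, and a per-gene Gaussian over whitened inducing
outputs with per-gene means and a shared Cholesky-parameterized covariance.
Kernel hyperparameters, tau^2_p and Z are point-estimated by the same Adam
loop.  Cells are minibatched uniformly; genes are minibatched proportionally
to the fraction of cells expressing them, with exact inverse-inclusion-
probability weights so the stochastic ELBO is unbiased.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import scipy.sparse as sp
from scipy import stats
from scipy.special import gammaln
from sklearn.decomposition import PCA

from . import _autodiff as ad
from .kernels import COMPONENTS, PRESETS, KernelParams, ParameterError

__all__ = [
    "ModelConfig",
    "VariationalState",
    "FitResult",
    "NumericalError",
    "student_t_logpdf",
    "normal_logpdf",
    "init_latent",
    "sample_gene_batch",
    "inclusion_probabilities",
    "elbo_estimate",
    "fit",
    "average_posterior_scale",
]


class NumericalError(RuntimeError):
    """Linear-algebra failure that persisted after jitter escalation."""


@dataclass
class ModelConfig:
    """Configuration of a tGPLVM fit.

    Defaults follow the reference training regime: nu = 4 degrees of
    freedom, minibatches of min(2500, N) cells and min(250, P) genes, 100
    passes through the data, Adam with learning rate 0.01.
    """

    q: int = 2
    nu: float = 4.0
    error_model: str = "student_t"  # student_t | normal
    kernel_preset: str = "full"  # full | m12 | rbf
    # The L1-weighted distance is exposed for fidelity to the composite
    # kernel's printed form, but it is not positive definite for Q > 1 and
    # makes the inducing Gram factorization fail during optimization; the
    # conventional weighted-L2 form is the fitting default.
    distance: str = "l2"  # l1 | l2
    n_inducing: int = 100
    cell_batch: int | None = None  # None -> min(2500, N)
    gene_batch: int | None = None  # None -> min(250, P)
    epochs: int = 100
    learning_rate: float = 0.01
    init: str = "pca"  # pca | random
    seed: int = 0
    n_mc: int = 1

    def __post_init__(self):
        if self.q < 1:
            raise ParameterError("q must be >= 1")
        if not self.nu > 0:
            raise ParameterError("nu must be positive")
        if self.error_model not in ("student_t", "normal"):
            raise ParameterError(f"unknown error model {self.error_model!r}")
        if self.kernel_preset not in PRESETS:
            raise ParameterError(f"unknown kernel preset {self.kernel_preset!r}")
        if self.distance not in ("l1", "l2"):
            raise ParameterError(f"unknown distance {self.distance!r}")
        for name in ("n_inducing", "cell_batch", "gene_batch", "epochs"):
            val = getattr(self, name)
            if val is not None and val < 1:
                raise ParameterError(f"{name} must be positive")
        if not self.learning_rate > 0:
            raise ParameterError("learning_rate must be positive")
        if self.init not in ("pca", "random"):
            raise ParameterError(f"unknown init {self.init!r}")


@dataclass
class VariationalState:
    """Variational parameters and point-estimated hyperparameters."""

    latent_means: np.ndarray  # N x Q
    latent_scales: np.ndarray  # N x Q, positive
    inducing_inputs: np.ndarray  # M x Q
    inducing_means: np.ndarray  # M x P (whitened, per gene)
    inducing_chol: np.ndarray  # M x M lower Cholesky of the shared covariance
    tau2: np.ndarray  # P, positive
    kernel_params: KernelParams

    def __post_init__(self):
        if np.any(self.latent_scales <= 0):
            raise ParameterError("latent scales must be strictly positive")
        if self.tau2.size and np.any(self.tau2 <= 0):
            raise ParameterError("tau2 must be strictly positive")


@dataclass
class FitResult:
    """Posterior summaries, hyperparameters and optimization trace."""

    posterior_means: np.ndarray  # N x Q
    posterior_scales: np.ndarray  # N x Q
    tau2: np.ndarray  # P
    kernel_params: KernelParams
    elbo_trace: np.ndarray
    config: ModelConfig
    state: VariationalState
    diverged: bool = False

    def ard_inverse_length_scales(self) -> dict[str, np.ndarray]:
        """Per-component, per-dimension relevance 1/ell (larger = more relevant)."""
        return {c: 1.0 / v for c, v in self.kernel_params.length_scales.items()}


# ----------------------------------------------------------------------
# Observation log-densities (public, scipy-backed)
# ----------------------------------------------------------------------


def student_t_logpdf(y, f, nu: float, tau2: float):
    """log StudentT(y; location f, dof nu, scale sqrt(tau2))."""
    if not nu > 0:
        raise ParameterError("nu must be positive")
    if not np.all(np.asarray(tau2) > 0):
        raise ParameterError("tau2 must be positive")
    return stats.t.logpdf(y, df=nu, loc=f, scale=np.sqrt(tau2))


def normal_logpdf(y, f, tau2: float):
    """log N(y; f, tau2)."""
    if not np.all(np.asarray(tau2) > 0):
        raise ParameterError("tau2 must be positive")
    return stats.norm.logpdf(y, loc=f, scale=np.sqrt(tau2))


# ----------------------------------------------------------------------
# Initialization
# ----------------------------------------------------------------------


def init_latent(Y, q: int, method: str = "pca", seed: int = 0):
    """Initial variational means and scales for the latent positions.

    ``pca``: first q principal-component scores, standardized to unit
    variance per column; scales start at 0.1.  ``random``: i.i.d. standard
    normal means; scales start at 1.0.
    """
    values = getattr(Y, "values", Y)
    if sp.issparse(values):
        values = values.toarray()
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    if n < 2:
        raise ValueError("need at least two cells")
    rng = np.random.default_rng(seed)
    if method == "random":
        return rng.standard_normal((n, q)), np.full((n, q), 1.0)
    if method != "pca":
        raise ParameterError(f"unknown init method {method!r}")
    if q > min(n, p):
        raise ValueError(f"q={q} exceeds min(N, P)={min(n, p)} for PCA init")
    scores = PCA(n_components=q, random_state=seed).fit_transform(values)
    sd = scores.std(axis=0)
    sd[sd == 0] = 1.0
    return scores / sd, np.full((n, q), 0.1)


def inclusion_probabilities(weights, size: int) -> np.ndarray:
    """Exact inclusion probabilities of size-proportional sampling.

    Proportional to ``weights`` with iterative capping at 1 (items whose
    proportional share exceeds one are always included and the remainder
    is rescaled), summing to ``size``.
    """
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    pi = np.zeros_like(w)
    free = w > 0
    remaining = size
    while True:
        total = w[free].sum()
        pi[free] = remaining * w[free] / total
        over = free & (pi > 1.0)
        if not over.any():
            break
        pi[over] = 1.0
        remaining -= int(over.sum())
        free = free & ~over
        if remaining <= 0 or not free.any():
            break
    return np.clip(pi, 0.0, 1.0)


def sample_gene_batch(nonzero_fraction, size: int, rng: np.random.Generator):
    """Sample distinct genes with probability proportional to expression rate.

    Randomized-order systematic probability-proportional-to-size sampling:
    the inclusion probability of gene g is exactly pi_g (see
    :func:`inclusion_probabilities`), so inverse-probability weights make
    weighted batch sums unbiased for the full-gene sums.  Returns
    ``(indices, weights)``.
    """
    frac = np.asarray(nonzero_fraction, dtype=float)
    expressible = np.flatnonzero(frac > 0)
    if expressible.size < size:
        raise ValueError(
            f"requested {size} genes but only {expressible.size} are expressed anywhere"
        )
    pi = inclusion_probabilities(frac, size)
    perm = rng.permutation(expressible)
    p = pi[perm]
    cum = np.concatenate([[0.0], np.cumsum(p)])
    cum[-1] = float(size)  # guard rounding
    points = rng.uniform() + np.arange(size)
    pos = np.searchsorted(cum, points, side="right") - 1
    chosen = perm[pos]
    return chosen, 1.0 / pi[chosen]


# ----------------------------------------------------------------------
# ELBO graph
# ----------------------------------------------------------------------


def _log_gamma_const(nu: float) -> float:
    return float(gammaln((nu + 1) / 2) - gammaln(nu / 2) - 0.5 * math.log(nu * math.pi))


def _params_from_state(state: VariationalState, config: ModelConfig) -> dict[str, np.ndarray]:
    params = {
        "mu": state.latent_means.copy(),
        "log_s": np.log(state.latent_scales),
        "Z": state.inducing_inputs.copy(),
        "m_u": state.inducing_means.copy(),
        "W_S": np.tril(state.inducing_chol, -1),
        "logd_S": np.log(np.diagonal(state.inducing_chol)),
        "log_tau2": np.log(state.tau2) if state.tau2.size else np.zeros(0),
    }
    for comp in PRESETS[config.kernel_preset]:
        params[f"log_sig2_{comp}"] = np.array(
            math.log(state.kernel_params.variances[comp])
        )
        params[f"log_len_{comp}"] = np.log(state.kernel_params.length_scales[comp])
    return params


def _state_from_params(params: Mapping[str, np.ndarray], config: ModelConfig) -> VariationalState:
    comps = PRESETS[config.kernel_preset]
    kp = KernelParams(
        variances={c: float(np.exp(params[f"log_sig2_{c}"])) for c in comps},
        length_scales={c: np.exp(params[f"log_len_{c}"]) for c in comps},
    )
    chol = np.tril(params["W_S"], -1) + np.diag(np.exp(params["logd_S"]))
    return VariationalState(
        latent_means=params["mu"].copy(),
        latent_scales=np.exp(params["log_s"]),
        inducing_inputs=params["Z"].copy(),
        inducing_means=params["m_u"].copy(),
        inducing_chol=chol,
        tau2=np.exp(params["log_tau2"]),
        kernel_params=kp,
    )


def _abs_diff(X, Z):
    """|x - z| tensor of shape (n, m, Q) for the L1 distance form."""
    n, q = X.shape
    m = Z.shape[0]
    diff = ad.reshape(X, (n, 1, q)) - ad.reshape(Z, (1, m, q))
    return ad.abs_(diff)


def _ad_kernel(r, r2, log_sig2, component):
    """One kernel component from the weighted distance r (and its square)."""
    sig2 = ad.exp(log_sig2)
    if component == "se":
        return sig2 * ad.exp(-0.5 * r2)
    if component == "mat12":
        return sig2 * ad.exp(-r)
    if component == "mat32":
        c = math.sqrt(3.0)
        return sig2 * ((1.0 + c * r) * ad.exp(-c * r))
    if component == "mat52":
        c = math.sqrt(5.0)
        return sig2 * ((1.0 + c * r + (5.0 / 3.0) * r2) * ad.exp(-c * r))
    raise ParameterError(f"unknown kernel component {component!r}")


def _ad_gram(X, Z, nodes, comps, metric):
    abs_stat = _abs_diff(X, Z) if metric == "l1" else None
    K = None
    for comp in comps:
        log_len = nodes[f"log_len_{comp}"]
        if metric == "l1":
            r = ad.sum_(abs_stat * ad.exp(-1.0 * log_len), axis=2)
            r2 = ad.square(r)
        else:
            r2 = ad.clip_min(ad.scaled_sqdist(X, Z, log_len), 1e-24)
            r = ad.sqrt(r2) if comp != "se" else r2  # SE only needs r^2
        k = _ad_kernel(r, r2, nodes[f"log_sig2_{comp}"], comp)
        K = k if K is None else K + k
    return K


def _build_elbo(nodes, Y_batch, cell_idx, gene_weights, n_total_cells, config, rng):
    """ELBO estimate as an AD node; inputs are parameter Nodes."""
    comps = PRESETS[config.kernel_preset]
    nb = len(cell_idx)
    scale_cells = n_total_cells / nb

    mu_b = ad.take_rows(nodes["mu"], cell_idx)
    log_s_b = ad.take_rows(nodes["log_s"], cell_idx)
    s_b = ad.exp(log_s_b)

    kl_x = 0.5 * ad.sum_(ad.square(mu_b) + ad.square(s_b) - 1.0 - 2.0 * log_s_b)
    elbo = -(scale_cells * kl_x)

    pb = Y_batch.shape[1] if Y_batch is not None else 0
    if pb:
        m = nodes["Z"].shape[0]
        w = np.asarray(gene_weights, dtype=float)
        w_row = w[None, :]
        sum_w = float(w.sum())

        # whitened inducing covariance S = C C^T
        C = ad.tril(nodes["W_S"], -1) + ad.diag_embed(ad.exp(nodes["logd_S"]))
        tr_S = ad.sum_(ad.square(C))
        logdet_S = 2.0 * ad.sum_(nodes["logd_S"])
        m_b = nodes["m_u_batch"]  # M x Pb node prepared by caller
        kl_u = 0.5 * (
            ad.sum_(ad.square(m_b) * w_row)
            + sum_w * (tr_S - float(m) - logdet_S)
        )
        elbo = elbo - kl_u

        total_var = None
        for comp in comps:
            v = ad.exp(nodes[f"log_sig2_{comp}"])
            total_var = v if total_var is None else total_var + v
        total_var_val = float(total_var.value)

        # one reparameterized draw of latent positions per MC sample
        ll_samples = []
        for _ in range(config.n_mc):
            eps = rng.standard_normal((nb, config.q))
            x = mu_b + s_b * eps

            jitter = 1e-6 * total_var_val
            Lm = None
            while Lm is None:
                try:
                    Kmm = _ad_gram(nodes["Z"], nodes["Z"], nodes, comps, config.distance)
                    Lm = ad.cholesky(Kmm + jitter * np.eye(m))
                except np.linalg.LinAlgError:
                    jitter = jitter * 10.0
                    if jitter > 1e-2 * total_var_val:
                        raise NumericalError(
                            "inducing Gram matrix not positive definite at jitter cap "
                            f"(total kernel variance {total_var_val:.3e}); the L1 "
                            "distance form is not guaranteed PD — consider distance='l2'"
                        ) from None
            Kmn = _ad_gram(nodes["Z"], x, nodes, comps, config.distance)
            A = ad.solve_lower(Lm, Kmn)  # M x nb
            mean_f = A.T @ m_b  # nb x Pb
            cond_var = ad.clip_min(total_var - ad.sum_(ad.square(A), axis=0), 1e-10)
            B = C.T @ A
            var_f = cond_var + ad.sum_(ad.square(B), axis=0)  # nb
            sd_f = ad.reshape(ad.sqrt(var_f), (nb, 1))
            zeta = rng.standard_normal((nb, pb))
            f = mean_f + sd_f * zeta

            log_tau2_b = nodes["log_tau2_batch"]  # Pb node
            tau2_b = ad.exp(log_tau2_b)
            resid2 = ad.square(Y_batch - f)
            if config.error_model == "student_t":
                nu = config.nu
                ll = (
                    _log_gamma_const(nu)
                    - 0.5 * log_tau2_b
                    - ((nu + 1.0) / 2.0) * ad.log1p(resid2 / (nu * tau2_b))
                )
            else:
                ll = -0.5 * (math.log(2 * math.pi) + log_tau2_b) - resid2 / (2.0 * tau2_b)
            ll_samples.append(ad.sum_(ll * w_row))
        ll_mean = ll_samples[0]
        for extra in ll_samples[1:]:
            ll_mean = ll_mean + extra
        elbo = elbo + (scale_cells / config.n_mc) * ll_mean
    return elbo


def _make_nodes(params, gene_idx):
    nodes = {k: ad.Node(v, requires_grad=True) for k, v in params.items()}
    if gene_idx is not None and len(gene_idx):
        nodes["m_u_batch"] = ad.transpose(
            ad.take_rows(ad.transpose(nodes["m_u"]), gene_idx)
        )
        nodes["log_tau2_batch"] = ad.take_rows(nodes["log_tau2"], gene_idx)
    return nodes


def elbo_estimate(state, Y_batch, cell_indices, gene_indices, weights, config, rng):
    """Monte-Carlo estimate of the minibatch-rescaled ELBO (no gradients).

    ``Y_batch`` is the cells x genes submatrix for the given index sets;
    ``weights`` are the genes' inverse inclusion probabilities.  The
    estimate is unbiased for the full-data ELBO under the sampling scheme
    and is deterministic given the state of ``rng``.
    """
    params = _params_from_state(state, config)
    nodes = _make_nodes(params, np.asarray(gene_indices, dtype=int))
    if Y_batch is None:
        Yb = np.zeros((len(cell_indices), 0))
    else:
        Yb = Y_batch.toarray() if sp.issparse(Y_batch) else np.asarray(Y_batch, dtype=float)
    value = _build_elbo(
        nodes,
        Yb if Yb.size else None,
        np.asarray(cell_indices, dtype=int),
        np.asarray(weights, dtype=float),
        state.latent_means.shape[0],
        config,
        rng,
    )
    return float(value.value)


# ----------------------------------------------------------------------
# Optimization
# ----------------------------------------------------------------------


class _Adam:
    def __init__(self, params, lr, b1=0.9, b2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g**2
            params[k] = params[k] + self.lr * (self.m[k] / b1t) / (
                np.sqrt(self.v[k] / b2t) + self.eps
            )


def _initial_state(values, config: ModelConfig) -> VariationalState:
    n, p = values.shape
    rng = np.random.default_rng(config.seed)
    mu, scales = init_latent(values, config.q, method=config.init, seed=config.seed)
    m_ind = min(config.n_inducing, n)
    idx = rng.choice(n, size=m_ind, replace=False)
    Z = mu[idx] + 0.01 * rng.standard_normal((m_ind, config.q))
    col_var = values.var(axis=0) if p else np.zeros(0)
    total_var = float(max(col_var.mean(), 1e-2)) if p else 1.0
    comps = PRESETS[config.kernel_preset]
    kp = KernelParams(
        variances={c: total_var / len(comps) for c in comps},
        length_scales={c: np.ones(config.q) for c in comps},
    )
    tau2 = np.maximum(0.5 * col_var, 1e-3) if p else np.zeros(0)
    return VariationalState(
        latent_means=mu,
        latent_scales=scales,
        inducing_inputs=Z,
        inducing_means=np.zeros((m_ind, p)),
        inducing_chol=np.eye(m_ind),
        tau2=tau2,
        kernel_params=kp,
    )


def fit(Y, config: ModelConfig) -> FitResult:
    """Fit the tGPLVM by stochastic gradient ascent on the ELBO.

    ``Y`` may be a CountMatrix, dense array or scipy sparse matrix of shape
    N x P.  Deterministic given ``config.seed`` (single-threaded).
    """
    values = getattr(Y, "values", Y)
    sparse_input = sp.issparse(values)
    if not sparse_input:
        values = np.asarray(values, dtype=float)
        if not np.isfinite(values).all():
            raise ValueError("Y contains NaN or inf")
        # non-negativity is a CountMatrix contract; the model itself accepts
        # real-valued observations (e.g. the zero-mean simulation benchmark)
    n, p = values.shape
    if n < 2:
        raise ValueError("need at least two cells")

    cell_batch = min(config.cell_batch or 2500, n)
    gene_batch = min(config.gene_batch or 250, p) if p else 0
    if (config.cell_batch or 0) > n or (p and (config.gene_batch or 0) > p):
        warnings.warn("batch size exceeds data dimension; clamped")

    dense_vals = values.toarray() if sparse_input else values
    state = _initial_state(dense_vals, config)
    params = _params_from_state(state, config)
    if p:
        frac = np.asarray((values > 0).sum(axis=0)).ravel() / n if sparse_input else (
            (values > 0).mean(axis=0)
        )
        if not frac.any():
            frac = np.full(p, 1.0)  # all-zero matrix: fall back to uniform
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    opt = _Adam(params, config.learning_rate)
    trace: list[float] = []
    diverged = False
    opt_keys = [k for k in params if params[k].size]

    for _ in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, cell_batch):
            cell_idx = order[start : start + cell_batch]
            if p:
                gene_idx, gweights = sample_gene_batch(frac, gene_batch, rng)
                Yb = dense_vals[np.ix_(cell_idx, gene_idx)]
            else:
                gene_idx, gweights, Yb = np.zeros(0, dtype=int), np.zeros(0), None
            nodes = _make_nodes(params, gene_idx)
            try:
                elbo = _build_elbo(nodes, Yb, cell_idx, gweights, n, config, rng)
            except NumericalError as err:
                warnings.warn(f"aborting optimization: {err}")
                diverged = True
                break
            if not np.isfinite(elbo.value):
                warnings.warn("ELBO became non-finite; aborting with last finite state")
                diverged = True
                break
            ad.backward(elbo)
            grads = {
                k: nodes[k].grad for k in opt_keys if nodes[k].grad is not None
            }
            opt.step(params, grads)
            trace.append(float(elbo.value))
        if diverged:
            break

    state = _state_from_params(params, config)
    return FitResult(
        posterior_means=state.latent_means,
        posterior_scales=state.latent_scales,
        tau2=state.tau2,
        kernel_params=state.kernel_params,
        elbo_trace=np.asarray(trace),
        config=config,
        state=state,
        diverged=diverged,
    )


def average_posterior_scale(result: FitResult, kind: str = "variance") -> float:
    """Mean posterior uncertainty of the latent positions.

    ``kind="variance"`` (default) averages the squared variational scales
    (the embedding's mean posterior variance); ``kind="scale"`` averages
    the scales themselves.
    """
    scales = result.posterior_scales
    if kind == "variance":
        return float(np.mean(scales**2))
    if kind == "scale":
        return float(np.mean(scales))
    raise ValueError(f"unknown kind {kind!r}")
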