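"""Evaluation procedures for estimated latent manifolds.

* Wasserstein-2 manifold-recovery distance between the row-normalized
  Euclidean distance matrices of an estimated and a ground-truth embedding,
  with the per-row optimal transport solved either exactly (linear
  programming, HiGHS) or with a batched Sinkhorn solver for large N.
* k-means clustering of an embedding against known labels, scored with
  normalized mutual information (NMI) and adjusted Rand score (ARS).
* Minimum-spanning-tree trajectory scaffolds on posterior means.
* Pearson correlation scans between latent dimensions and gene expression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog
from scipy.sparse import csr_matrix
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score

__all__ = [
    "DegenerateInputError",
    "EvaluationReport",
    "row_normalized_distance_matrix",
    "w2_manifold_distance",
    "kmeans_cluster_scores",
    "nmi",
    "ars",
    "mst_trajectory",
    "pearson_gene_correlations",
]


class DegenerateInputError(ValueError):
    """All observations coincide; distances carry no information."""


@dataclass
class EvaluationReport:
    """Container for whichever evaluation outputs were requested."""

    w2: float | None = None
    nmi_mean: float | None = None
    nmi_sd: float | None = None
    ars_mean: float | None = None
    ars_sd: float | None = None
    mst_edges: list[tuple[int, int, float]] | None = None
    gene_correlations: np.ndarray | None = None

    def to_dict(self) -> dict:
        out = {}
        for key in ("w2", "nmi_mean", "nmi_sd", "ars_mean", "ars_sd"):
            val = getattr(self, key)
            if val is not None:
                out[key] = float(val)
        if self.mst_edges is not None:
            out["mst_edges"] = [[int(i), int(j), float(w)] for i, j, w in self.mst_edges]
        if self.gene_correlations is not None:
            out["gene_correlations"] = np.where(
                np.isnan(self.gene_correlations), None, self.gene_correlations
            ).tolist()
        return out


def row_normalized_distance_matrix(X) -> np.ndarray:
    """Row-stochastic Euclidean distance profile of each observation.

    Entry (i, j) is ||x_i - x_j|| / sum_k ||x_i - x_k||; rows sum to one
    and the diagonal is zero.  Scale-invariant by construction.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D array with at least two observations")
    D = cdist(X, X)
    sums = D.sum(axis=1)
    if np.all(D == 0):
        raise DegenerateInputError("all observations are identical")
    return D / sums[:, None]


def _exact_row_ot(a, b, cost) -> float:
    """Minimal <pi, cost> over couplings of a and b via HiGHS."""
    n = a.size
    # marginal constraints; drop one redundant row for full rank
    rows, cols, data = [], [], []
    for j in range(n):
        for k in range(n):
            idx = j * n + k
            rows.append(j)
            cols.append(idx)
            data.append(1.0)
            if k < n - 1:
                rows.append(n + k)
                cols.append(idx)
                data.append(1.0)
    A_eq = csr_matrix((data, (rows, cols)), shape=(2 * n - 1, n * n))
    b_eq = np.concatenate([a, b[:-1]])
    res = linprog(cost.ravel(), A_eq=A_eq, b_eq=b_eq, bounds=(0, None), method="highs")
    if not res.success:
        raise RuntimeError(f"OT linear program failed: {res.message}")
    return float(res.fun)


def _sinkhorn_rows(A, B, cost, epsilon, max_iter=400, tol=1e-6) -> np.ndarray:
    """Entropic OT of every row pair (A[i], B[i]) under a shared cost.

    Runs all rows simultaneously (two N x N matrix products per sweep)
    with epsilon-annealing from a safe start down to ``epsilon``.
    Returns per-row transport costs <pi_i, cost>.
    """
    eps = max(epsilon, 1e-12)
    eps_list = []
    e = max(cost.max() / 20.0, eps)
    while e > eps * 1.001:
        eps_list.append(e)
        e /= 5.0
    eps_list.append(eps)

    logU = np.zeros_like(A)
    logV = np.zeros_like(B)
    for e in eps_list:
        K = np.exp(-cost / e)
        U = np.exp(logU / e)
        V = np.exp(logV / e)
        last = e == eps_list[-1]
        for it in range(max_iter if last else 25):
            U = np.where(A > 0, A / np.maximum(V @ K.T, 1e-300), 0.0)
            V = np.where(B > 0, B / np.maximum(U @ K, 1e-300), 0.0)
            if last and it % 10 == 9:
                err = np.abs(U * (V @ K.T) - A).sum(axis=1).max()
                if err < tol:
                    break
        with np.errstate(divide="ignore"):
            logU = np.where(U > 0, e * np.log(U), 0.0)
            logV = np.where(V > 0, e * np.log(V), 0.0)
    KC = K * cost
    return np.einsum("ij,ij->i", U, V @ KC.T)


def w2_manifold_distance(
    X_est,
    X_true,
    order: int = 2,
    method: str = "auto",
    epsilon: float = 0.01,
    return_rows: bool = False,
):
    """Average per-observation Wasserstein distance between distance profiles.

    For each observation i the discrete optimal-transport problem is solved
    between row i of the row-normalized distance matrix of ``X_est`` and of
    ``X_true``.  The ground cost between support points j and k is the true
    pairwise distance, normalized by the mean off-diagonal true distance so
    the metric is invariant to similarity transforms of either embedding.
    Under the default ``order=2`` the transported cost is squared and the
    square root of the per-row optimum is averaged (true W2); ``order=1``
    gives W1.

    ``method``: "exact" (LP per row), "sinkhorn" (batched entropic
    approximation, regularization ``epsilon`` on the normalized squared
    cost), or "auto" (exact for N <= 64).
    """
    X_est = np.asarray(X_est, dtype=float)
    X_true = np.asarray(X_true, dtype=float)
    if X_est.shape[0] != X_true.shape[0]:
        raise ValueError(
            f"row mismatch: estimate has {X_est.shape[0]} rows, truth {X_true.shape[0]}"
        )
    n = X_est.shape[0]
    A = row_normalized_distance_matrix(X_est)
    B = row_normalized_distance_matrix(X_true)
    D_true = cdist(X_true, X_true)
    scale = D_true.sum() / (n * (n - 1))
    cost = (D_true / scale) ** order

    if method == "auto":
        method = "exact" if n <= 64 else "sinkhorn"
    if method == "exact":
        row_costs = np.array([_exact_row_ot(A[i], B[i], cost) for i in range(n)])
    elif method == "sinkhorn":
        row_costs = _sinkhorn_rows(A, B, cost, epsilon)
    else:
        raise ValueError(f"unknown method {method!r}")
    rows = np.maximum(row_costs, 0.0) ** (1.0 / order)
    return (rows, float(rows.mean())) if return_rows else float(rows.mean())


def nmi(a, b) -> float:
    """Normalized mutual information I(a;b)/sqrt(H(a) H(b)).

    Degenerate convention: if either partition has a single cluster the
    score is 1.0 when the two partitions are identical as partitions and
    0.0 otherwise (library conventions differ here).
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("label vectors differ in length")
    na, nb = len(np.unique(a)), len(np.unique(b))
    if na == 1 or nb == 1:
        return 1.0 if na == nb == 1 else 0.0
    return float(normalized_mutual_info_score(a, b, average_method="geometric"))


def ars(a, b) -> float:
    """Adjusted Rand score (pair-counting agreement, chance corrected)."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("label vectors differ in length")
    if a.size < 2:
        raise ValueError("need at least two observations")
    return float(adjusted_rand_score(a, b))


def kmeans_cluster_scores(embedding, labels, repeats: int = 10, base_seed: int = 0):
    """k-means on the embedding scored against labels over several restarts.

    k equals the number of distinct labels; each repeat uses k-means++
    seeding with seed ``base_seed + repeat``.  Returns
    ``(nmi_mean, nmi_sd, ars_mean, ars_sd)``.
    """
    embedding = np.asarray(embedding, dtype=float)
    labels = np.asarray(labels)
    if embedding.shape[0] != labels.shape[0]:
        raise ValueError("embedding and labels differ in length")
    k = len(np.unique(labels))
    if k < 2:
        raise ValueError("need at least two distinct labels")
    if k >= embedding.shape[0]:
        raise ValueError(f"k={k} must be smaller than N={embedding.shape[0]}")
    nmis, arss = [], []
    for r in range(repeats):
        km = KMeans(
            n_clusters=k, init="k-means++", n_init=1, max_iter=300,
            random_state=base_seed + r,
        ).fit(embedding)
        nmis.append(nmi(labels, km.labels_))
        arss.append(ars(labels, km.labels_))
    return (
        float(np.mean(nmis)),
        float(np.std(nmis)),
        float(np.mean(arss)),
        float(np.std(arss)),
    )


def mst_trajectory(embedding) -> list[tuple[int, int, float]]:
    """Minimum spanning tree of the complete Euclidean graph on an embedding.

    Kruskal's algorithm with deterministic tie-breaking: edges are sorted
    by (weight, i, j).  Returns N-1 edges ``(i, j, weight)`` with i < j.
    """
    X = np.asarray(embedding, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least two points")
    if not np.isfinite(X).all():
        raise ValueError("embedding contains NaN or inf")
    n = X.shape[0]
    D = cdist(X, X)
    if np.all(D == 0):
        warnings.warn("all points identical; returning an arbitrary zero-weight tree")
    iu, ju = np.triu_indices(n, k=1)
    w = D[iu, ju]
    order = np.lexsort((ju, iu, w))
    parent = np.arange(n)

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    edges = []
    for idx in order:
        i, j = int(iu[idx]), int(ju[idx])
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            edges.append((i, j, float(w[idx])))
            if len(edges) == n - 1:
                break
    return edges


def pearson_gene_correlations(embedding, counts) -> np.ndarray:
    """Pearson r between each latent dimension and each gene's values.

    ``counts`` may be a CountMatrix, a dense array or a sparse matrix of
    shape N x P.  Constant genes yield NaN (flagged, not zero).
    Returns a Q x P matrix.
    """
    X = np.asarray(embedding, dtype=float)
    values = getattr(counts, "values", counts)
    if hasattr(values, "toarray"):
        values = values.toarray()
    Y = np.asarray(values, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("embedding and counts differ in number of cells")
    if X.shape[0] < 3:
        raise ValueError("need at least three cells for a correlation")
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    sx = np.sqrt((Xc**2).sum(axis=0))
    sy = np.sqrt((Yc**2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        R = (Xc.T @ Yc) / np.outer(sx, sy)
    R[:, sy == 0] = np.nan
    return R
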