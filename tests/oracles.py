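"""Independent brute-force oracles used to validate production algorithms.

These deliberately avoid the code paths (and, where possible, the libraries)
they are checking: transport plans are enumerated over basic feasible
solutions, spanning trees via Pruefer sequences, partition scores via raw
contingency tables and pair counting, and the GPLVM log marginal likelihood
via dense Gauss-Hermite quadrature.
"""

import itertools

import numpy as np
from scipy.special import logsumexp


def ot_cost_bruteforce(a, b, cost):
    """Exact optimal transport cost by enumerating basic feasible solutions.

    A vertex of the transportation polytope uses at most (2n-1) cells whose
    bipartite graph is acyclic; enumerate all cell subsets of that size,
    solve the marginal equations, and keep the feasible minimum.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n = a.size
    cells = [(j, k) for j in range(n) for k in range(n)]
    m = 2 * n - 1
    best = np.inf
    # marginal constraint matrix (drop last column constraint: redundant)
    for subset in itertools.combinations(cells, m):
        A = np.zeros((m, m))
        for col, (j, k) in enumerate(subset):
            A[j, col] = 1.0
            if k < n - 1:
                A[n + k, col] = 1.0
        rhs = np.concatenate([a, b[:-1]])
        try:
            x = np.linalg.solve(A, rhs)
        except np.linalg.LinAlgError:
            continue
        if np.any(x < -1e-9):
            continue
        val = sum(max(xi, 0.0) * cost[j, k] for xi, (j, k) in zip(x, subset))
        best = min(best, val)
    return best


def pruefer_mst_weight(D):
    """Minimum spanning tree weight by enumerating all labeled trees."""
    n = D.shape[0]
    if n == 2:
        return D[0, 1]
    best = np.inf
    for seq in itertools.product(range(n), repeat=n - 2):
        edges = _pruefer_decode(seq, n)
        w = sum(D[i, j] for i, j in edges)
        best = min(best, w)
    return best


def _pruefer_decode(seq, n):
    degree = [1] * n
    for s in seq:
        degree[s] += 1
    edges = []
    seq = list(seq)
    leaves = sorted(i for i in range(n) if degree[i] == 1)
    import heapq

    heapq.heapify(leaves)
    for s in seq:
        leaf = heapq.heappop(leaves)
        edges.append((leaf, s))
        degree[s] -= 1
        if degree[s] == 1:
            heapq.heappush(leaves, s)
    u, v = leaves
    edges.append((u, v))
    return edges


def contingency(a, b):
    ua, ia = np.unique(a, return_inverse=True)
    ub, ib = np.unique(b, return_inverse=True)
    C = np.zeros((ua.size, ub.size), dtype=int)
    for x, y in zip(ia, ib):
        C[x, y] += 1
    return C


def nmi_bruteforce(a, b):
    """I(a;b)/sqrt(H(a)H(b)) from the raw contingency table."""
    C = contingency(a, b)
    n = C.sum()
    pij = C / n
    pi = pij.sum(axis=1)
    pj = pij.sum(axis=0)
    mi = 0.0
    for i in range(C.shape[0]):
        for j in range(C.shape[1]):
            if pij[i, j] > 0:
                mi += pij[i, j] * np.log(pij[i, j] / (pi[i] * pj[j]))
    ha = -np.sum(pi * np.log(pi, where=pi > 0, out=np.zeros_like(pi)))
    hb = -np.sum(pj * np.log(pj, where=pj > 0, out=np.zeros_like(pj)))
    if ha == 0 or hb == 0:
        return 1.0 if ha == hb == 0 else 0.0
    return mi / np.sqrt(ha * hb)


def ars_bruteforce(a, b):
    """Adjusted Rand index by explicit enumeration of all point pairs."""
    a = np.asarray(a)
    b = np.asarray(b)
    n = a.size
    n11 = n00 = n10 = n01 = 0
    for i in range(n):
        for j in range(i + 1, n):
            sa = a[i] == a[j]
            sb = b[i] == b[j]
            n11 += sa and sb
            n00 += (not sa) and (not sb)
            n10 += sa and not sb
            n01 += (not sa) and sb
    total = n * (n - 1) / 2
    ri = (n11 + n00) / total
    # expected index from marginal pair counts
    pa = (n11 + n10) / total
    pb = (n11 + n01) / total
    expected = pa * pb + (1 - pa) * (1 - pb)
    if expected == 1.0:
        return 1.0
    return (ri - expected) / (1 - expected)


def gplvm_log_marginal_quadrature(Y, kernel_fn, tau2, n_nodes=9):
    """log p(Y) for a normal-error GPLVM with Q=1 by Gauss-Hermite quadrature.

    Integrates the closed-form conditional p(Y | X) = prod_p N(y_p; 0,
    K(X) + diag(tau2_p)) against the N(0, I_N) latent prior on a dense
    tensor-product Gauss-Hermite grid (probabilists' weights).
    """
    Y = np.asarray(Y, dtype=float)
    n, p = Y.shape
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_nodes)
    logw = np.log(weights) - 0.5 * np.log(2 * np.pi)
    grids = np.meshgrid(*([nodes] * n), indexing="ij")
    X = np.stack([g.ravel() for g in grids], axis=-1)  # (n_nodes^n, n)
    logW = np.zeros(X.shape[0])
    for d, g in enumerate(np.meshgrid(*([logw] * n), indexing="ij")):
        logW += g.ravel()
    # batched conditional log-likelihoods
    out = np.empty(X.shape[0])
    for i, x in enumerate(X):
        K = kernel_fn(x[:, None])
        ll = 0.0
        for j in range(p):
            cov = K + tau2[j] * np.eye(n)
            L = np.linalg.cholesky(cov)
            alpha = np.linalg.solve(L, Y[:, j])
            ll += (
                -0.5 * alpha @ alpha
                - np.log(np.diagonal(L)).sum()
                - 0.5 * n * np.log(2 * np.pi)
            )
        out[i] = ll
    # GH with probabilists' weights integrates against exp(-x^2/2); the
    # normal-prior density is folded into logW above
    return logsumexp(out + logW)
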