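"""Markov clustering (MCL) of small weighted graphs.

MCL alternates expansion (squaring a column-stochastic matrix — random-walk
flow spreads) with inflation (elementwise powering and renormalising —
strong flow is rewarded) until the matrix is idempotent; the support of the
limit decomposes the graph into clusters. The implementation is tuned for
the many few-hundred-vertex subgraphs this package clusters: it iterates on
a dense float32 matrix while the iterate is dense and switches to CSR once
inflation has thinned it out, pruning entries below a small floor as the
standard MCL implementations do.
"""

from __future__ import annotations

import warnings

import numpy as np
import scipy.sparse as sp

__all__ = ["markov_cluster"]


def markov_cluster(weights: np.ndarray, inflation: float = 2.0,
                   max_iter: int = 100, tol: float = 1e-6,
                   prune: float = 1e-5, self_loops: str = "max",
                   attractor_tol: float = 1e-4) -> list[np.ndarray]:
    """Cluster an undirected weighted graph given as a dense (k, k) matrix.

    Parameters
    ----------
    weights : symmetric nonnegative matrix; the diagonal is ignored and
        replaced according to ``self_loops``.
    inflation : elementwise power applied after each expansion (> 1;
        larger values give finer clusters).
    self_loops : 'max' adds a per-vertex loop equal to its maximum incident
        edge weight (regularisation; isolated vertices get 1).
    attractor_tol : converged-matrix entries above this are treated as
        support when reading off clusters.

    Returns
    -------
    A partition of range(k) as a list of sorted index arrays, ordered by
    their smallest vertex. Deterministic for fixed input and parameters.
    """
    A = np.array(weights, dtype=np.float32)
    k = A.shape[0]
    if k == 0:
        return []
    if A.shape != (k, k):
        raise ValueError("weights must be square")
    if inflation <= 1:
        raise ValueError("inflation must be > 1")
    np.fill_diagonal(A, 0.0)
    if self_loops == "max":
        loops = A.max(axis=0)
        loops[loops <= 0] = 1.0
    elif self_loops == "one":
        loops = np.ones(k, dtype=np.float32)
    else:
        raise ValueError(f"unknown self_loops mode {self_loops!r}")
    np.fill_diagonal(A, loops)

    M = A / A.sum(axis=0, keepdims=True)
    is_sparse = False
    converged = False
    for _ in range(max_iter):
        if not is_sparse:
            M2 = M @ M
            np.power(M2, inflation, out=M2)
            M2 /= M2.sum(axis=0, keepdims=True)
            M2[M2 < prune] = 0.0
            M2 /= M2.sum(axis=0, keepdims=True)
            diff = float(np.abs(M2 - M).max())
            M = M2
            if (M > 0).mean() < 0.1 and k > 64:
                M = sp.csr_array(M)
                is_sparse = True
        else:
            M2 = M @ M
            M2.data **= inflation
            inv = 1.0 / np.maximum(M2.sum(axis=0), np.finfo(np.float32).tiny)
            M2 = M2 @ sp.diags_array(inv, format="csr")
            M2.data[M2.data < prune] = 0.0
            M2.eliminate_zeros()
            inv = 1.0 / np.maximum(M2.sum(axis=0), np.finfo(np.float32).tiny)
            M2 = M2 @ sp.diags_array(inv, format="csr")
            diff = float(abs(M2 - M).max())
            M = M2
        if diff < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"MCL did not converge within {max_iter} iterations "
            f"(last max change {diff:.2e}); clustering the current iterate",
            stacklevel=2,
        )
    if is_sparse:
        M = M.toarray()
    return _read_clusters(M, attractor_tol)


def _read_clusters(M: np.ndarray, tau: float) -> list[np.ndarray]:
    """Clusters of the (near-)idempotent MCL limit.

    Attractors are vertices with positive return probability (diagonal mass).
    Two attractors belong to one attractor system when some vertex flows to
    both; every vertex joins the system of its largest-probability attractor
    (ties: lowest attractor index, via argmax's first-hit rule).
    """
    k = M.shape[0]
    attractors = np.flatnonzero(np.diag(M) > tau)
    if attractors.size == 0:  # pathological; treat the graph as one cluster
        return [np.arange(k)]
    support = M[attractors] > tau  # (a, k)
    overlap = support @ support.T
    n_sys, sys_label = sp.csgraph.connected_components(
        sp.csr_array(overlap), directed=False
    )
    best_attr = np.argmax(M[attractors], axis=0)  # (k,)
    vertex_sys = sys_label[best_attr]
    clusters = [np.flatnonzero(vertex_sys == s) for s in range(n_sys)]
    clusters = [c for c in clusters if c.size]
    clusters.sort(key=lambda c: int(c[0]))
    return clusters
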