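"""Personalized PageRank embedding with shrinking.

Each node u gets one feature vector: the stationary distribution of a random
walk that, at every step, follows a weight-proportional outgoing edge with
probability alpha and restarts at u with probability 1 - alpha,

    gamma_u(i) <- alpha * sum_{j -> i} w_ji / d_j * gamma_u(j)
                  + (1 - alpha) * [i == u],

approximated by power iteration until the L1 difference between successive
iterates falls below ``tol``.  "Shrinking" restricts the iteration to the
nodes reachable from u (one BFS); unreachable entries are exactly zero, which
changes nothing numerically but skips dead coordinates.

Undirected edges are treated as two directed edges.  Dangling nodes (possible
only when isolated nodes were admitted explicitly) send their mass back to
the restart vector so the iterate stays a probability distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from joblib import Parallel, delayed
from scipy.sparse.csgraph import breadth_first_order

from .embedding import EmbeddingMatrix
from .graph import Graph


@dataclass(frozen=True)
class PPRParams:
    """Damping factor alpha, L1 convergence tolerance, iteration cap."""

    alpha: float = 0.85
    tol: float = 1e-6
    max_iter: int = 100_000

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie strictly in (0, 1)")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


def _transition(G: Graph) -> sp.csr_matrix:
    """Column-oriented transition operator: (W x)_i = sum_j w_ji/d_j x_j."""
    A, degrees, _ = G.adjacency()
    inv_d = np.zeros_like(degrees)
    nz = degrees > 0
    inv_d[nz] = 1.0 / degrees[nz]
    # row-normalize then transpose: entry (i, j) = w_ji / d_j
    return sp.csr_matrix(A.multiply(inv_d[:, None]).T)


def _ppr_on_operator(Wt: sp.csr_matrix, degrees: np.ndarray, u: int,
                     params: PPRParams) -> np.ndarray:
    n = Wt.shape[0]
    reachable = breadth_first_order(Wt, u, directed=False,
                                    return_predecessors=False)
    sub = np.sort(np.asarray(reachable))
    Ws = Wt[np.ix_(sub, sub)].tocsr()
    dangling = degrees[sub] == 0
    v = np.zeros(sub.size)
    v[np.searchsorted(sub, u)] = 1.0
    x = v.copy()
    alpha = params.alpha
    for _ in range(params.max_iter):
        lost = alpha * float(x[dangling].sum()) if dangling.any() else 0.0
        x_new = alpha * (Ws @ x) + (1.0 - alpha + lost) * v
        residual = float(np.abs(x_new - x).sum())
        x = x_new
        if residual < params.tol:
            break
    else:
        raise RuntimeError(
            f"PPR power iteration for node {u} did not converge in "
            f"{params.max_iter} iterations (last residual {residual:.3e})"
        )
    out = np.zeros(n)
    out[sub] = x
    return out


def ppr_vector(G: Graph, u: int, params: PPRParams = PPRParams()) -> np.ndarray:
    """Personalized PageRank vector seeded at internal node index ``u``.

    Returns a probability vector over all nodes (sums to 1 within 1e-9);
    nodes unreachable from ``u`` get exactly zero mass.
    """
    if not 0 <= u < G.n_nodes:
        raise ValueError(f"node index {u} out of range")
    _, degrees, _ = G.adjacency()
    return _ppr_on_operator(_transition(G), degrees, u, params)


def embed_ppr(G: Graph, params: PPRParams = PPRParams(), n_jobs: int = 1,
              normalize: bool = False) -> EmbeddingMatrix:
    """Stack the PPR vectors of all nodes into an |N| x |N| embedding.

    Rows are computed independently (embarrassingly parallel via joblib);
    the result is bitwise identical for any ``n_jobs``.  ``normalize``
    optionally L2-normalizes rows before clustering (off by default; raw
    stationary distributions live on the simplex and are scale-sensitive
    under Euclidean k-means).
    """
    Wt = _transition(G)
    _, degrees, _ = G.adjacency()
    if n_jobs == 1:
        rows = [_ppr_on_operator(Wt, degrees, u, params)
                for u in range(G.n_nodes)]
    else:
        rows = Parallel(n_jobs=n_jobs)(
            delayed(_ppr_on_operator)(Wt, degrees, u, params)
            for u in range(G.n_nodes)
        )
    X = np.vstack(rows)
    if normalize:
        norms = np.linalg.norm(X, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        X = X / norms
    return EmbeddingMatrix(
        values=X,
        node_ids=list(G.node_ids),
        provenance={"method": "ppr", "alpha": params.alpha, "tol": params.tol,
                    "max_iter": params.max_iter, "normalized": bool(normalize)},
    )
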