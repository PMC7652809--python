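"""NetMF-style node embedding by closed-form matrix factorization.

DeepWalk with window ``T`` and ``b`` negative samples implicitly factorizes

    M = log( vol(G) * (1/T) * sum_{r=1..T} (D^-1 A)^r * D^-1 / b )

where ``A`` is the weighted adjacency, ``D`` the diagonal of generalized
degrees and ``vol(G) = sum_ij A_ij``.  We build this matrix explicitly with a
truncated logarithm ``log(max(., 1))`` (entries that would go negative or to
-inf are clipped to 0, the standard NetMF construction) and take a rank-d
truncated SVD; the embedding is ``U_d sqrt(Sigma_d)``.

Dense matrix powers are used throughout: the target graphs are at most a few
thousand nodes, where dense BLAS is both exact and fastest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.utils.extmath import randomized_svd

from .embedding import EmbeddingMatrix
from .graph import Graph

logger = logging.getLogger(__name__)

DEFAULT_SEED = 42


@dataclass(frozen=True)
class NetMFParams:
    """Context window size T, negative samples b, embedding dimension d."""

    T: int = 5
    b: int = 1
    d: int = 32

    def __post_init__(self) -> None:
        if self.T < 1 or self.b < 1 or self.d < 1:
            raise ValueError("T, b and d must all be >= 1")


def deepwalk_matrix(G: Graph, T: int, b: int) -> np.ndarray:
    """Closed-form DeepWalk co-occurrence matrix with truncated log.

    Returns the |N| x |N| matrix ``log(max(vol(G)/(T*b) * sum_r P^r D^-1, 1))``
    with ``P = D^-1 A``.  All entries are finite and >= 0.

    Raises
    ------
    ValueError
        If any node has zero degree (isolated nodes must be removed before
        embedding; the random walk is undefined there).
    """
    if T < 1 or b < 1:
        raise ValueError("T and b must be >= 1")
    A, degrees, vol = G.adjacency()
    if vol <= 0:
        raise ValueError("graph volume must be positive")
    zero = np.flatnonzero(degrees == 0)
    if zero.size:
        ids = [G.node_ids[i] for i in zero[:10]]
        raise ValueError(
            f"nodes with zero degree {ids}: remove isolated nodes before embedding"
        )
    Ad = A.toarray()
    inv_d = 1.0 / degrees
    P = Ad * inv_d[:, None]  # random-walk transition matrix D^-1 A
    S = np.zeros_like(P)
    Pr = np.eye(G.n_nodes)
    for _ in range(T):
        Pr = Pr @ P
        S += Pr
    S /= T
    M_raw = (vol / b) * S * inv_d[None, :]
    M = np.log(np.maximum(M_raw, 1.0))
    density = float(np.count_nonzero(M)) / max(M.size, 1)
    logger.info("deepwalk matrix: %d x %d, density %.3f after truncation",
                *M.shape, density)
    return M


def factorize(M: np.ndarray, d: int, seed: int = DEFAULT_SEED,
              node_ids: list[str] | None = None) -> EmbeddingMatrix:
    """Rank-d truncated SVD of M; embedding rows are ``U_d sqrt(Sigma_d)``.

    Deterministic for a fixed ``seed`` (randomized SVD solver).
    """
    M = np.asarray(M, dtype=np.float64)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("M must be square")
    if not np.all(np.isfinite(M)):
        raise ValueError("M contains non-finite entries")
    n = M.shape[0]
    if not 1 <= d <= n:
        raise ValueError(f"embedding dimension d={d} must be in [1, {n}]")
    if d == n:
        U, s, _ = np.linalg.svd(M, full_matrices=False)
    else:
        U, s, _ = randomized_svd(M, n_components=d, random_state=seed)
    emb = U[:, :d] * np.sqrt(np.maximum(s[:d], 0.0))
    if node_ids is None:
        node_ids = [str(i) for i in range(n)]
    return EmbeddingMatrix(
        values=emb,
        node_ids=node_ids,
        provenance={"method": "netmf-svd", "d": int(d), "seed": int(seed),
                    "scaling": "U*sqrt(Sigma)"},
    )


def embed_netmf(G: Graph, params: NetMFParams,
                seed: int = DEFAULT_SEED) -> EmbeddingMatrix:
    """Compose :func:`deepwalk_matrix` and :func:`factorize`."""
    M = deepwalk_matrix(G, params.T, params.b)
    emb = factorize(M, params.d, seed=seed, node_ids=list(G.node_ids))
    emb.provenance.update(
        {"method": "netmf", "T": int(params.T), "b": int(params.b)}
    )
    return emb
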