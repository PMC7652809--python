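"""Silhouette community detection: cluster node embeddings with mini-batch
k-means and select the number of communities k by a two-stage Silhouette
optimization.

The search solves

    P_final(G) = argmax_{k in K, p in P} SilhouetteGlobal(k, p)

over candidate cluster counts k and embedding settings p.  Candidate ks are
first swept on a coarse arithmetic grid (``validRange``: every gamma-th k
between k_min and K), then the neighborhood of the coarse optimum is
inspected exhaustively (fine phase), scanning outward so the stopping window
w (halt after w consecutive non-improving evaluations) is meaningful near
the optimum.  The sampling interval gamma can be derived from the maximum
expected community count as gamma = K^(2/3).

Silhouette of a point i in cluster C_i:

    a(i) = mean distance of i to the rest of C_i          (cohesion)
    b(i) = min over other clusters of mean distance to it (separation)
    s(i) = (b(i) - a(i)) / max(a(i), b(i)),  s(i) = 0 if |C_i| = 1

with Euclidean distances; the global score is the mean of s(i) over nodes
(optionally over a seeded uniform subsample — the full computation is
O(|N|^2 d)).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import MiniBatchKMeans

from .embedding import EmbeddingMatrix
from .graph import Graph
from .netmf import NetMFParams, embed_netmf
from .partition import Partition
from .ppr import PPRParams, embed_ppr

logger = logging.getLogger(__name__)

__all__ = [
    "SCDConfig",
    "SearchTrace",
    "Evaluation",
    "minibatch_kmeans",
    "silhouette_point",
    "silhouette_global",
    "valid_range",
    "gamma_estimate",
    "coarse_search",
    "fine_search",
    "scd_detect",
    "embedding_grid",
]

SUBSAMPLE_THRESHOLD = 5000  # above this, Silhouette defaults to a subsample


def embedding_grid(name: str = "fast") -> list[dict]:
    """Named embedding-parameter grids.

    ``"full"`` is the study grid: negative samples {1,5,20} x window
    {1,3,5,10,30,50} x dimension {16,32,64,128,256} (90 NetMF settings).
    ``"fast"`` is a two-setting default for desk-scale runs.
    """
    if name == "full":
        return [
            {"method": "netmf", "T": T, "b": b, "d": d}
            for b in (1, 5, 20)
            for T in (1, 3, 5, 10, 30, 50)
            for d in (16, 32, 64, 128, 256)
        ]
    if name == "fast":
        return [
            {"method": "netmf", "T": 3, "b": 1, "d": 16},
            {"method": "netmf", "T": 5, "b": 1, "d": 32},
        ]
    raise ValueError(f"unknown grid preset {name!r}")


@dataclass
class SCDConfig:
    """Search parameters for Silhouette community detection.

    Attributes
    ----------
    k_min, K
        Candidate cluster counts span [k_min, K]; K defaults to |N| when
        left as None (the validRange-[5, |N|, 10] convention).
    gamma
        Coarse sampling interval; ``"auto"`` derives ceil(K^(2/3)).
    w
        Stopping window: a phase halts after w consecutive evaluations
        without Silhouette improvement.
    embedding_grid
        List of embedding settings, each ``{"method": "netmf"|"ppr", ...}``.
    subsample
        Silhouette subsample size; None = automatic (full below
        ``SUBSAMPLE_THRESHOLD`` nodes, 5000 above).
    normalize_across_dims
        Min-max normalize Silhouettes within each embedding dimension before
        the cross-grid argmax (scores are only compared across settings of
        different dimensionality after this rescaling).
    """

    k_min: int = 5
    K: int | None = None
    gamma: int | str = "auto"
    w: int = 5
    embedding_grid: list[dict] = field(default_factory=lambda: embedding_grid("fast"))
    seed: int = 42
    batch_size: int = 1024
    n_init: int = 3
    subsample: int | None = None
    normalize_across_dims: bool = True

    def __post_init__(self) -> None:
        if self.k_min < 2:
            raise ValueError("k_min must be >= 2")
        if self.K is not None and self.K < self.k_min:
            raise ValueError("K must be >= k_min")
        if self.gamma != "auto" and int(self.gamma) < 1:
            raise ValueError("gamma must be >= 1 or 'auto'")
        if self.w < 1:
            raise ValueError("stopping window w must be >= 1")


@dataclass
class Evaluation:
    """One (phase, embedding setting, k, Silhouette) record."""

    phase: str  # "coarse" | "fine"
    params_id: int
    k: int
    silhouette: float
    normalized: float | None = None


@dataclass
class SearchTrace:
    """Ordered record of Silhouette evaluations with the selected optimum."""

    evaluations: list[Evaluation] = field(default_factory=list)
    best_k: int | None = None
    best_silhouette: float = -np.inf
    best_normalized: float | None = None
    best_params_id: int | None = None
    best_labels: np.ndarray | None = None

    def record(self, ev: Evaluation) -> None:
        self.evaluations.append(ev)

    def to_records(self) -> list[dict]:
        return [
            {"phase": e.phase, "params_id": e.params_id, "k": e.k,
             "silhouette": e.silhouette, "normalized": e.normalized}
            for e in self.evaluations
        ]


# ---------------------------------------------------------------------------
# clustering


def minibatch_kmeans(
    X: np.ndarray | EmbeddingMatrix,
    k: int,
    seed: int = 42,
    batch_size: int = 1024,
    n_init: int = 3,
) -> tuple[np.ndarray, np.ndarray]:
    """Mini-batch k-means with k-means++ initialization.

    Returns ``(labels, centers)`` with labels relabeled to ``0..k'-1`` over
    the non-empty clusters only (the mini-batch optimizer may leave clusters
    empty).  If k exceeds the number of distinct rows, the distinct rows are
    clustered instead and a warning is emitted.
    """
    if isinstance(X, EmbeddingMatrix):
        X = X.values
    X = np.asarray(X, dtype=np.float64)
    n = X.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds number of points {n}")
    if k == 1:
        return np.zeros(n, dtype=np.int64), X.mean(axis=0, keepdims=True)

    fit_X, inverse = X, None
    if k > 1:
        uniq, inverse = np.unique(X, axis=0, return_inverse=True)
        if k > uniq.shape[0]:
            warnings.warn(
                f"k={k} exceeds the {uniq.shape[0]} distinct rows; "
                "clustering the distinct rows instead",
                stacklevel=2,
            )
            k = uniq.shape[0]
            fit_X = uniq
        else:
            inverse = None

    km = MiniBatchKMeans(
        n_clusters=k,
        init="k-means++",
        n_init=n_init,
        batch_size=batch_size,
        random_state=seed,
    )
    labels = km.fit_predict(fit_X)
    if inverse is not None:
        labels = labels[inverse]
    # drop empty clusters from the label space
    nonempty, labels = np.unique(labels, return_inverse=True)
    return labels.astype(np.int64), km.cluster_centers_[nonempty]


# ---------------------------------------------------------------------------
# Silhouette


def _silhouette_samples(X: np.ndarray, labels: np.ndarray,
                        rows: np.ndarray | None = None) -> np.ndarray:
    """s(i) for the requested rows (default: all), against all points."""
    labels = np.asarray(labels)
    clusters, codes = np.unique(labels, return_inverse=True)
    if clusters.size < 2:
        raise ValueError("Silhouette requires at least 2 non-empty clusters")
    if rows is None:
        rows = np.arange(X.shape[0])
    D = cdist(X[rows], X)
    k = clusters.size
    sizes = np.bincount(codes, minlength=k).astype(np.float64)
    sums = np.empty((rows.size, k))
    for c in range(k):
        sums[:, c] = D[:, codes == c].sum(axis=1)
    own = codes[rows]
    own_size = sizes[own]
    # d(i, i) = 0 sits inside the own-cluster sum, so no correction needed
    with np.errstate(invalid="ignore", divide="ignore"):
        a = sums[np.arange(rows.size), own] / (own_size - 1)
    means = sums / sizes[None, :]
    means[np.arange(rows.size), own] = np.inf
    b = means.min(axis=1)
    s = np.zeros(rows.size)
    ok = own_size > 1
    denom = np.maximum(a[ok], b[ok])
    nz = denom > 0
    vals = np.zeros(ok.sum())
    vals[nz] = (b[ok][nz] - a[ok][nz]) / denom[nz]
    s[ok] = vals
    return s


def silhouette_point(i: int, labels, X: np.ndarray) -> float:
    """Silhouette s(i) of a single point; 0 for a singleton cluster."""
    X = np.asarray(X, dtype=np.float64)
    return float(_silhouette_samples(X, labels, rows=np.array([i]))[0])


def silhouette_global(labels, X: np.ndarray,
                      subsample: int | None = None,
                      seed: int | None = None) -> float:
    """Mean Silhouette over all points, or over a seeded uniform subsample.

    A subsample of m points costs O(m |N| d) instead of O(|N|^2 d); each
    sampled point is still scored against the full point set.
    """
    X = np.asarray(X, dtype=np.float64)
    n = X.shape[0]
    rows = None
    if subsample is not None and subsample < n:
        rng = np.random.default_rng(seed)
        rows = np.sort(rng.choice(n, size=subsample, replace=False))
    return float(_silhouette_samples(X, np.asarray(labels), rows=rows).mean())


# ---------------------------------------------------------------------------
# candidate-k grids


def gamma_estimate(K: int) -> int:
    """Sampling interval gamma = K^(2/3), rounded up, at least 1.

    Exact cubes are recognized despite floating-point (1000^(2/3) = 100).
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    x = float(K) ** (2.0 / 3.0)
    nearest = round(x)
    if abs(x - nearest) < 1e-9:
        return max(1, int(nearest))
    return max(1, math.ceil(x))


def valid_range(k_min: int, K: int, gamma: int) -> list[int]:
    """Arithmetic candidate grid k_min, k_min+gamma, ... with K appended."""
    if K < k_min:
        raise ValueError("K must be >= k_min")
    if gamma < 1:
        raise ValueError("gamma must be >= 1")
    ks = list(range(k_min, K + 1, gamma))
    if ks[-1] != K:
        ks.append(K)
    return ks


# ---------------------------------------------------------------------------
# the two-phase search


def _resolve(config: SCDConfig, n: int) -> tuple[int, int, int, int | None]:
    K = min(config.K if config.K is not None else n, n)
    k_min = min(config.k_min, K)
    gamma = gamma_estimate(K) if config.gamma == "auto" else int(config.gamma)
    if config.subsample is not None:
        sub = config.subsample
    else:
        sub = SUBSAMPLE_THRESHOLD if n > SUBSAMPLE_THRESHOLD else None
    return k_min, K, gamma, sub


def _evaluate_k(X: np.ndarray, k: int, config: SCDConfig,
                subsample: int | None) -> tuple[float, np.ndarray] | None:
    """Cluster at k and score; None when fewer than 2 clusters realize."""
    labels, _ = minibatch_kmeans(X, k, seed=config.seed,
                                 batch_size=config.batch_size,
                                 n_init=config.n_init)
    if np.unique(labels).size < 2:
        return None
    score = silhouette_global(labels, X, subsample=subsample, seed=config.seed)
    return score, labels


def _sweep(X: np.ndarray, ks, phase: str, config: SCDConfig,
           subsample: int | None, trace: SearchTrace, params_id: int,
           evaluated: set[int]) -> None:
    """Evaluate ks in order with the w-window stopping rule, updating trace."""
    stall = 0
    for k in ks:
        if k in evaluated:
            continue
        evaluated.add(k)
        result = _evaluate_k(X, k, config, subsample)
        if result is None:
            logger.warning("%s phase: k=%d realized <2 clusters, skipped",
                           phase, k)
            continue
        score, labels = result
        trace.record(Evaluation(phase=phase, params_id=params_id, k=k,
                                silhouette=score))
        improved = score > trace.best_silhouette or (
            score == trace.best_silhouette
            and trace.best_k is not None and k < trace.best_k
        )
        if score > trace.best_silhouette:
            stall = 0
        else:
            stall += 1
        if improved:
            trace.best_k = k
            trace.best_silhouette = score
            trace.best_params_id = params_id
            trace.best_labels = labels
        if stall >= config.w:
            logger.info("%s phase halted after %d non-improving evaluations",
                        phase, stall)
            break


def coarse_search(X: np.ndarray | EmbeddingMatrix, config: SCDConfig,
                  params_id: int = 0) -> SearchTrace:
    """Coarse sweep of k over validRange with the stopping rule."""
    if isinstance(X, EmbeddingMatrix):
        X = X.values
    n = X.shape[0]
    k_min, K, gamma, subsample = _resolve(config, n)
    if K < 2:
        raise ValueError("K < 2: no valid number of clusters to evaluate")
    ks = [k for k in valid_range(max(2, k_min), K, gamma) if k <= n]
    trace = SearchTrace()
    _sweep(X, ks, "coarse", config, subsample, trace, params_id,
           evaluated=set())
    if trace.best_k is None:
        raise ValueError("coarse search: every candidate k failed to produce "
                         ">= 2 clusters")
    return trace


def fine_search(X: np.ndarray | EmbeddingMatrix, config: SCDConfig,
                k_star: int, trace: SearchTrace | None = None,
                params_id: int = 0) -> SearchTrace:
    """Exhaustive scan of the +-gamma neighborhood of the coarse optimum.

    Candidates are visited outward from ``k_star`` (k*+1, k*-1, k*+2, ...),
    skipping ks already evaluated, under the same stopping window; the merged
    trace retains the global best, so the fine-phase best never falls below
    the coarse-phase best.
    """
    if isinstance(X, EmbeddingMatrix):
        X = X.values
    n = X.shape[0]
    _, K, gamma, subsample = _resolve(config, n)
    if trace is None:
        trace = SearchTrace()
        trace.best_k, trace.best_silhouette = k_star, -np.inf
    evaluated = {e.k for e in trace.evaluations if e.params_id == params_id}
    lo, hi = max(2, k_star - gamma), min(K, n, k_star + gamma)
    ks: list[int] = []
    for delta in range(1, gamma + 1):
        for k in (k_star + delta, k_star - delta):
            if lo <= k <= hi:
                ks.append(k)
    _sweep(X, ks, "fine", config, subsample, trace, params_id, evaluated)
    return trace


def _embed_setting(G: Graph, setting: dict, seed: int) -> EmbeddingMatrix:
    setting = dict(setting)
    method = setting.pop("method")
    if method == "netmf":
        return embed_netmf(G, NetMFParams(**setting), seed=seed)
    if method == "ppr":
        normalize = setting.pop("normalize", False)
        n_jobs = setting.pop("n_jobs", 1)
        return embed_ppr(G, PPRParams(**setting), n_jobs=n_jobs,
                         normalize=normalize)
    raise ValueError(f"unknown embedding method {method!r}")


def _setting_dim(setting: dict, n: int) -> int:
    return int(setting.get("d", n))


def scd_detect(G: Graph, config: SCDConfig) -> tuple[Partition, SearchTrace]:
    """Full Silhouette community detection over an embedding grid.

    For every embedding setting: embed, coarse sweep, fine sweep.  The winner
    maximizes the global Silhouette; when settings of different embedding
    dimensionality compete, scores are first min-max normalized within each
    dimension (disable via ``config.normalize_across_dims``).  Ties break
    toward smaller k, then smaller d, then earlier grid position.  Returns
    the winning partition labeled by external node IDs plus the merged trace.
    """
    grid: list[dict] = []
    seen = set()
    for setting in config.embedding_grid:
        key = tuple(sorted(setting.items()))
        if key not in seen:
            seen.add(key)
            grid.append(setting)
    if not grid:
        raise ValueError("embedding grid is empty")

    merged = SearchTrace()
    per_setting: list[dict] = []
    for pid, setting in enumerate(grid):
        emb = _embed_setting(G, setting, seed=config.seed)
        X = emb.values
        trace = coarse_search(X, config, params_id=pid)
        trace = fine_search(X, config, trace.best_k, trace=trace,
                            params_id=pid)
        merged.evaluations.extend(trace.evaluations)
        per_setting.append({
            "params_id": pid,
            "setting": setting,
            "d": _setting_dim(setting, G.n_nodes),
            "best_k": trace.best_k,
            "best_silhouette": trace.best_silhouette,
            "best_labels": trace.best_labels,
        })

    # min-max normalization of Silhouettes within each embedding dimension
    dims = {_setting_dim(s, G.n_nodes) for s in grid}
    if config.normalize_across_dims and len(dims) >= 1:
        by_dim: dict[int, list[float]] = {d: [] for d in dims}
        pid_dim = {rec["params_id"]: rec["d"] for rec in per_setting}
        for ev in merged.evaluations:
            by_dim[pid_dim[ev.params_id]].append(ev.silhouette)
        ranges = {d: (min(v), max(v)) for d, v in by_dim.items() if v}

        def norm(d: int, s: float) -> float:
            lo, hi = ranges[d]
            return 1.0 if hi == lo else (s - lo) / (hi - lo)

        for ev in merged.evaluations:
            ev.normalized = norm(pid_dim[ev.params_id], ev.silhouette)
        for rec in per_setting:
            rec["score"] = norm(rec["d"], rec["best_silhouette"])
    else:
        for ev in merged.evaluations:
            ev.normalized = ev.silhouette
        for rec in per_setting:
            rec["score"] = rec["best_silhouette"]

    winner = min(
        per_setting,
        key=lambda r: (-r["score"], r["best_k"], r["d"], r["params_id"]),
    )
    merged.best_k = winner["best_k"]
    merged.best_silhouette = winner["best_silhouette"]
    merged.best_normalized = winner["score"]
    merged.best_params_id = winner["params_id"]
    merged.best_labels = winner["best_labels"]

    labels = [int(x) for x in winner["best_labels"]]
    partition = Partition(node_ids=list(G.node_ids), labels=labels)
    logger.info("selected k=%d (silhouette %.4f) with setting %s",
                partition.k, merged.best_silhouette, winner["setting"])
    return partition, merged
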