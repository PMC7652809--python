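"""Benchmark-network generators with planted ground truth.

Two families:

* LFR (Lancichinetti–Fortunato–Radicchi) graphs — power-law degrees and
  community sizes with a mixing parameter mu controlling what fraction of a
  node's edges leave its community.  These mirror the synthetic study design
  (node counts {100..10000} x average degree {15,30,50} x maximum degree
  {10,50,100,500} x mixing {0.1..0.9}, degree exponent 2, community
  exponent 1).  The construction is implemented here directly: a truncated
  power-law degree sequence calibrated to the requested average, power-law
  community sizes, a capacity-respecting community assignment, and
  configuration-model wiring of intra- and inter-community stubs.
* Stochastic block models — Bernoulli planted partitions, used as fast and
  always-feasible test fixtures (LFR generation is stochastic and can fail
  for awkward parameter combinations).

Both generators are deterministic per seed and return a (Graph, Partition)
pair whose partition covers exactly the returned node set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .graph import Graph
from .partition import Partition

logger = logging.getLogger(__name__)

__all__ = ["LFRSpec", "SBMSpec", "generate_lfr", "generate_sbm",
           "benchmark_grid", "grid_combinations"]


@dataclass(frozen=True)
class LFRSpec:
    """Parameters of one LFR benchmark graph."""

    n: int
    avg_degree: float
    max_degree: int
    mixing: float
    degree_exponent: float = 2.0
    community_exponent: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.mixing <= 1:
            raise ValueError("mixing must lie in [0, 1]")
        if not self.avg_degree <= self.max_degree < self.n:
            raise ValueError(
                f"need avg_degree <= max_degree < n, got "
                f"avg={self.avg_degree}, max={self.max_degree}, n={self.n}"
            )
        if self.degree_exponent <= 1:
            raise ValueError("degree_exponent must be > 1")
        if self.community_exponent < 1:
            raise ValueError("community_exponent must be >= 1")


@dataclass(frozen=True)
class SBMSpec:
    """Planted-partition stochastic block model parameters."""

    block_sizes: tuple[int, ...]
    p_in: float
    p_out: float
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.block_sizes):
            raise ValueError("all blocks must be non-empty")
        if not 0 <= self.p_out < self.p_in <= 1:
            raise ValueError("need 0 <= p_out < p_in <= 1")


def _truncated_powerlaw(rng: np.random.Generator, lo: int, hi: int,
                        exponent: float, size: int) -> np.ndarray:
    """Draw integers with P(x) proportional to x^-exponent on [lo, hi]."""
    support = np.arange(lo, hi + 1)
    p = support.astype(float) ** (-exponent)
    p /= p.sum()
    return rng.choice(support, size=size, p=p)


def _calibrated_min_degree(avg: float, exponent: float, max_degree: int) -> int:
    """Smallest-degree cutoff whose truncated power law averages ``avg``."""
    support = np.arange(1, max_degree + 1, dtype=float)
    weights = support ** (-exponent)
    # conditional mean of the law truncated to [m, max_degree], per m
    tail_w = np.cumsum(weights[::-1])[::-1]
    tail_xw = np.cumsum((support * weights)[::-1])[::-1]
    means = tail_xw / tail_w
    m = int(np.argmin(np.abs(means - avg))) + 1
    if abs(means[m - 1] - avg) > 0.25 * avg:
        raise ValueError(
            f"average degree {avg} is unreachable with exponent {exponent} "
            f"and max degree {max_degree} (closest attainable "
            f"{means[m - 1]:.1f})")
    return m


def _community_sizes(rng: np.random.Generator, n: int, exponent: float,
                     s_min: int, s_max: int) -> list[int] | None:
    """Power-law community sizes summing exactly to n, or None on failure."""
    if s_min > s_max or s_min > n:
        return None
    sizes: list[int] = []
    total = 0
    while total < n:
        s = int(_truncated_powerlaw(rng, s_min, min(s_max, n), exponent, 1)[0])
        sizes.append(s)
        total += s
    excess = total - n
    # spread the overshoot across communities, keeping every size >= s_min
    order = rng.permutation(len(sizes))
    for i in order:
        if excess == 0:
            break
        cut = min(excess, sizes[i] - s_min)
        sizes[i] -= cut
        excess -= cut
    if excess:
        return None
    return sizes


def _assign_communities(rng: np.random.Generator, intra: np.ndarray,
                        sizes: list[int]) -> np.ndarray | None:
    """Place each node in a community of size > its intra-degree."""
    n = intra.size
    sizes_arr = np.array(sizes)
    free = sizes_arr.copy()
    membership = np.full(n, -1, dtype=np.int64)
    # hardest nodes (largest intra-degree) first, random order within ties
    order = np.lexsort((rng.permutation(n), -intra))
    for u in order:
        ok = np.flatnonzero((free > 0) & (sizes_arr > intra[u]))
        if ok.size == 0:
            return None
        # weight by free slots so large communities fill proportionally
        c = rng.choice(ok, p=free[ok] / free[ok].sum())
        membership[u] = c
        free[c] -= 1
    return membership


def _pair_stubs(rng: np.random.Generator, stubs: np.ndarray,
                accept, existing: set[tuple[int, int]],
                repair_rounds: int = 10) -> list[tuple[int, int]]:
    """Configuration-model pairing with bounded re-pairing of rejects.

    ``accept(u, v)`` decides whether a candidate pair may become an edge;
    rejected stubs are reshuffled and re-paired up to ``repair_rounds``
    times, then silently discarded (a small, standard degree loss).
    """
    edges: list[tuple[int, int]] = []
    pool = stubs.copy()
    for _ in range(repair_rounds):
        if pool.size < 2:
            break
        pool = rng.permutation(pool)
        leftovers: list[int] = []
        for a, b in zip(pool[0::2], pool[1::2]):
            u, v = (int(a), int(b)) if a < b else (int(b), int(a))
            if u != v and (u, v) not in existing and accept(u, v):
                existing.add((u, v))
                edges.append((u, v))
            else:
                leftovers.extend((int(a), int(b)))
        if pool.size % 2:
            leftovers.append(int(pool[-1]))
        pool = np.array(leftovers, dtype=np.int64)
    return edges


def _lfr_attempt(spec: LFRSpec, rng: np.random.Generator
                 ) -> tuple[list[tuple[int, int]], np.ndarray] | None:
    n = spec.n
    m = _calibrated_min_degree(spec.avg_degree, spec.degree_exponent,
                               spec.max_degree)
    degrees = _truncated_powerlaw(rng, m, spec.max_degree,
                                  spec.degree_exponent, n)
    intra = np.rint((1.0 - spec.mixing) * degrees).astype(np.int64)
    # community sizes live between the smallest and largest intra-degrees,
    # capped near max_degree as in the original construction
    s_min = max(2, int(intra.min()) + 1)
    s_max = min(n, max(spec.max_degree, int(intra.max()) + 1))
    sizes = _community_sizes(rng, n, spec.community_exponent, s_min, s_max)
    if sizes is None:
        return None
    # the largest community must be able to host the largest intra-degree;
    # grow it by moving members from other communities when necessary
    need = int(intra.max()) + 1
    big = max(range(len(sizes)), key=sizes.__getitem__)
    donors = [i for i in range(len(sizes)) if i != big]
    while sizes[big] < need and donors:
        i = donors[-1]
        move = min(need - sizes[big], sizes[i] - s_min)
        sizes[big] += move
        sizes[i] -= move
        if sizes[i] <= s_min:
            donors.pop()
    if sizes[big] < need:
        return None
    sizes = [s for s in sizes if s > 0]
    membership = _assign_communities(rng, intra, sizes)
    if membership is None:
        return None

    existing: set[tuple[int, int]] = set()
    edges: list[tuple[int, int]] = []
    # intra-community wiring: a configuration model inside each community
    for c in range(len(sizes)):
        members = np.flatnonzero(membership == c)
        stubs = np.repeat(members, intra[members])
        if stubs.size % 2:
            drop = rng.choice(members[intra[members] > 0])
            keep = np.flatnonzero(stubs == drop)[0]
            stubs = np.delete(stubs, keep)
        edges.extend(_pair_stubs(rng, stubs, lambda u, v: True, existing))
    # inter-community wiring: global pairing, edges must cross communities
    inter = degrees - intra
    stubs = np.repeat(np.arange(n), inter)
    if stubs.size % 2:
        stubs = stubs[:-1]
    edges.extend(_pair_stubs(
        rng, stubs, lambda u, v: membership[u] != membership[v], existing))
    touched = np.zeros(n, dtype=bool)
    for u, v in edges:
        touched[u] = touched[v] = True
    if not touched.all():
        return None  # a node lost every stub to discards; retry
    return edges, membership


def generate_lfr(spec: LFRSpec, max_tries: int = 10) -> tuple[Graph, Partition]:
    """Sample one LFR graph with its planted community partition.

    Each node draws a degree from a truncated power law (the low cutoff is
    calibrated so the expected degree matches ``avg_degree``), keeps a
    ``1 - mixing`` fraction of its edges inside its community, and the two
    stub populations are wired by configuration models.  Attempts whose
    community-size sequence or assignment cannot be realized are retried
    with derived seeds up to ``max_tries`` times before raising an error
    naming the offending parameters.  Identical specs always return
    identical edge sets.
    """
    for attempt in range(max_tries):
        rng = np.random.default_rng((spec.seed, attempt))
        result = _lfr_attempt(spec, rng)
        if result is not None:
            break
    else:
        raise RuntimeError(
            f"LFR generation failed after {max_tries} attempts for {spec}: "
            "could not realize a community-size sequence and assignment; "
            "the parameter combination may be unsatisfiable")
    edges, membership = result
    node_ids = [str(v) for v in range(spec.n)]
    graph = Graph.from_edges(
        [(str(u), str(v), 1.0) for u, v in sorted(edges)], nodes=node_ids)
    truth = Partition(node_ids=node_ids,
                      labels=[f"c{membership[v]}" for v in range(spec.n)])
    return graph, truth


def generate_sbm(spec: SBMSpec) -> tuple[Graph, Partition]:
    """Sample a planted-partition graph by independent Bernoulli edges."""
    sizes = list(spec.block_sizes)
    n = sum(sizes)
    block = np.repeat(np.arange(len(sizes)), sizes)
    rng = np.random.default_rng(spec.seed)
    iu, ju = np.triu_indices(n, k=1)
    p = np.where(block[iu] == block[ju], spec.p_in, spec.p_out)
    keep = rng.random(p.size) < p
    node_ids = [str(i) for i in range(n)]
    edges = [(str(i), str(j), 1.0) for i, j in zip(iu[keep], ju[keep])]
    graph = Graph.from_edges(edges, nodes=node_ids)
    truth = Partition(node_ids=node_ids,
                      labels=[f"b{b}" for b in block])
    return graph, truth


_FULL_NODES = (100, 500, 750, 1000, 2500, 5000, 10000)
_REDUCED_NODES = (100, 500, 1000)
_AVG_DEGREES = (15, 30, 50)
_MAX_DEGREES = (10, 50, 100, 500)
_MIXINGS = (0.1, 0.2, 0.5, 0.7, 0.9)


def grid_combinations(scale: str = "full") -> list[tuple[int, int, int, float]]:
    """Raw (n, avg_degree, max_degree, mixing) cross product, unfiltered.

    The full scale is the 7 x 3 x 4 x 5 = 420-combination study design
    (degree exponent 2, community exponent 1); ``"reduced"`` restricts node
    counts to {100, 500, 1000}.
    """
    if scale == "full":
        node_counts = _FULL_NODES
    elif scale == "reduced":
        node_counts = _REDUCED_NODES
    else:
        raise ValueError(f"unknown scale {scale!r}")
    return [(n, avg, mx, mu)
            for n in node_counts
            for avg in _AVG_DEGREES
            for mx in _MAX_DEGREES
            for mu in _MIXINGS]


def benchmark_grid(scale: str = "reduced", base_seed: int = 0) -> list[LFRSpec]:
    """Feasible LFR specs of the study grid at the requested scale.

    Combinations violating avg_degree <= max_degree < n can never be
    realized and are dropped with a log entry; each surviving spec gets a
    distinct seed derived from ``base_seed`` and its grid position.
    """
    specs: list[LFRSpec] = []
    dropped = 0
    for idx, (n, avg, mx, mu) in enumerate(grid_combinations(scale)):
        if avg <= mx < n:
            specs.append(LFRSpec(n=n, avg_degree=avg, max_degree=mx,
                                 mixing=mu, seed=base_seed + idx))
        else:
            dropped += 1
    if dropped:
        logger.info("benchmark grid (%s): dropped %d infeasible combinations",
                    scale, dropped)
    return specs
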