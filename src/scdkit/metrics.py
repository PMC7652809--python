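"""Partition-quality measures: NMI, ARI, and weighted modularity.

NMI(Y, C) = 2 I(Y;C) / (H(Y) + H(C)) with natural-log entropies; ARI is the
pair-counting Rand index adjusted for chance over the contingency table;
modularity is

    Q = 1/(2m) sum_{v,w} [A_vw - k_v k_w / (2m)] delta(c_v, c_w)

with weighted adjacency, generalized degrees and m = vol(G)/2, computed via
the equivalent per-community aggregation.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .graph import Graph
from .partition import Partition

__all__ = ["contingency_table", "nmi", "ari", "modularity"]


def _aligned_codes(truth: Partition, pred: Partition) -> tuple[np.ndarray, np.ndarray]:
    if set(truth.node_ids) != set(pred.node_ids):
        only_t = sorted(set(truth.node_ids) - set(pred.node_ids))[:5]
        only_p = sorted(set(pred.node_ids) - set(truth.node_ids))[:5]
        raise ValueError(
            f"partitions cover different node sets "
            f"(only in truth: {only_t}, only in pred: {only_p})"
        )
    order = truth.node_ids
    return truth.aligned_codes(order), pred.aligned_codes(order)


def contingency_table(truth: Partition, pred: Partition) -> np.ndarray:
    """Counts n_ij of nodes in truth-class i and predicted-cluster j."""
    y, c = _aligned_codes(truth, pred)
    table = np.zeros((y.max() + 1, c.max() + 1), dtype=np.int64)
    np.add.at(table, (y, c), 1)
    return table


def _entropy(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum())


def nmi(truth: Partition, pred: Partition) -> float:
    """Normalized mutual information in [0, 1].

    Degenerate cases: both partitions trivial (single cluster each) gives
    1.0 — they are necessarily identical; exactly one trivial gives 0.0.
    """
    table = contingency_table(truth, pred).astype(np.float64)
    hy = _entropy(table.sum(axis=1))
    hc = _entropy(table.sum(axis=0))
    if hy == 0.0 and hc == 0.0:
        return 1.0
    if hy == 0.0 or hc == 0.0:
        return 0.0
    # I(Y;C) = H(Y) + H(C) - H(Y,C): for identical partitions the joint
    # entropy cancels one marginal bitwise, making the ratio exactly 1
    hj = _entropy(table.ravel())
    mi = max(hy + hc - hj, 0.0)
    return min(2.0 * mi / (hy + hc), 1.0)


def ari(truth: Partition, pred: Partition) -> float:
    """Adjusted Rand index in [-1, 1]; 1 iff identical up to relabeling."""
    table = contingency_table(truth, pred).astype(np.float64)
    n = table.sum()

    def comb2(x):
        return x * (x - 1) / 2.0

    sum_ij = comb2(table).sum()
    a = comb2(table.sum(axis=1)).sum()
    b = comb2(table.sum(axis=0)).sum()
    expected = a * b / comb2(n)
    maximum = (a + b) / 2.0
    if maximum == expected:
        # both trivial or both all-singletons: identical partitions
        return 1.0
    return float((sum_ij - expected) / (maximum - expected))


def modularity(G: Graph, P: Partition) -> float:
    """Newman modularity Q of a partition, with edge weights throughout.

    Every graph node must carry a label (and vice versa).  Computed per
    community: Q = sum_c [ w_in_c / (2m) - (deg_c / (2m))^2 ] where w_in_c
    sums A over ordered within-community pairs and deg_c sums generalized
    degrees.
    """
    if set(P.node_ids) != set(G.node_ids):
        missing = sorted(set(G.node_ids) - set(P.node_ids))[:5]
        extra = sorted(set(P.node_ids) - set(G.node_ids))[:5]
        raise ValueError(
            f"partition does not cover the graph exactly "
            f"(uncovered: {missing}, unknown: {extra})"
        )
    codes = P.aligned_codes(list(G.node_ids))
    A, degrees, vol = G.adjacency()
    if vol == 0:
        raise ValueError("modularity undefined on an edgeless graph")
    k = codes.max() + 1
    member = sp.csr_matrix(
        (np.ones_like(codes, dtype=np.float64),
         (np.arange(codes.size), codes)),
        shape=(codes.size, k),
    )
    w_in = np.asarray((member.T @ A @ member).diagonal())  # ordered pairs
    deg_c = np.asarray(member.T @ degrees).ravel()
    two_m = vol
    return float((w_in / two_m - (deg_c / two_m) ** 2).sum())
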