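"""Independent brute-force oracles used to validate the fast implementations.

Everything here is written with explicit loops straight from the defining
formulas, on purpose: these functions must not share any code path with the
package under test.
"""

from __future__ import annotations

import math

import numpy as np


def brute_silhouette_samples(X: np.ndarray, labels) -> np.ndarray:
    """Per-point Silhouette via the textbook O(N^2) double loop."""
    X = np.asarray(X, dtype=float)
    labels = list(labels)
    n = len(labels)
    clusters = sorted(set(labels), key=str)
    members = {c: [i for i in range(n) if labels[i] == c] for c in clusters}
    if len(clusters) < 2:
        raise ValueError("need at least two clusters")

    def dist(i, j):
        return math.dist(X[i], X[j])

    s = np.zeros(n)
    for i in range(n):
        own = labels[i]
        if len(members[own]) == 1:
            s[i] = 0.0
            continue
        a = sum(dist(i, j) for j in members[own] if j != i) / (len(members[own]) - 1)
        b = min(
            sum(dist(i, j) for j in members[c]) / len(members[c])
            for c in clusters if c != own
        )
        m = max(a, b)
        s[i] = 0.0 if m == 0 else (b - a) / m
    return s


def brute_silhouette_global(X: np.ndarray, labels) -> float:
    return float(brute_silhouette_samples(X, labels).mean())


def double_sum_modularity(A: np.ndarray, labels) -> float:
    """Literal Q = 1/(2m) sum_vw [A_vw - k_v k_w / (2m)] delta(c_v, c_w)."""
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    k = A.sum(axis=1)
    two_m = A.sum()
    q = 0.0
    for v in range(n):
        for w in range(n):
            if labels[v] == labels[w]:
                q += A[v, w] - k[v] * k[w] / two_m
    return q / two_m


def pair_counting_ari(truth, pred) -> float:
    """ARI by enumerating all node pairs (index, expected, max form)."""
    n = len(truth)
    same_t = same_p = same_both = 0
    pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            pairs += 1
            st = truth[i] == truth[j]
            sp = pred[i] == pred[j]
            same_t += st
            same_p += sp
            same_both += st and sp
    expected = same_t * same_p / pairs
    maximum = (same_t + same_p) / 2
    if maximum == expected:
        return 1.0
    return (same_both - expected) / (maximum - expected)


def exhaustive_best_k(X: np.ndarray, ks, cluster_fn) -> tuple[int, float]:
    """argmax_k of the global Silhouette over every k in ks (no stopping)."""
    best_k, best_s = None, -np.inf
    for k in ks:
        labels = cluster_fn(X, k)
        if len(set(labels.tolist())) < 2:
            continue
        s = brute_silhouette_global(X, labels.tolist())
        if s > best_s:
            best_k, best_s = k, s
    return best_k, best_s
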