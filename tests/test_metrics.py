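"""NMI, ARI and weighted modularity, cross-checked against brute-force
pair counting, the literal modularity double sum, and scikit-learn."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score

from scdkit import Graph, Partition, ari, modularity, nmi

from oracles import double_sum_modularity, pair_counting_ari


def _partition(labels, ids=None):
    ids = ids or [f"n{i}" for i in range(len(labels))]
    return Partition(node_ids=ids, labels=list(labels))


class TestNMI:
    def test_identical_partitions_score_one(self):
        p = _partition(["a", "a", "b", "b", "c"])
        assert nmi(p, p) == 1.0

    def test_single_cluster_prediction_scores_zero(self):
        t = _partition([0, 0, 1, 1])
        p = _partition(["x"] * 4)
        assert nmi(t, p) == 0.0

    def test_independent_marginals_score_zero(self):
        t = _partition(["a", "a", "b", "b"])
        p = _partition(["a", "b", "a", "b"])
        assert nmi(t, p) == pytest.approx(0.0, abs=1e-12)

    def test_both_trivial_partitions_score_one(self):
        p = _partition([0, 0, 0])
        assert nmi(p, p) == 1.0

    def test_matches_sklearn(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            a = rng.integers(0, 4, size=50)
            b = rng.integers(0, 3, size=50)
            assert nmi(_partition(a), _partition(b)) == pytest.approx(
                normalized_mutual_info_score(a, b), abs=1e-10)

    def test_node_set_mismatch_rejected(self):
        t = _partition([0, 1], ids=["a", "b"])
        p = _partition([0, 1], ids=["a", "c"])
        with pytest.raises(ValueError, match="different node sets"):
            nmi(t, p)


class TestARI:
    def test_identical_partitions_score_one(self):
        p = _partition([0, 1, 1, 2, 2, 2])
        assert ari(p, p) == 1.0

    def test_crossed_two_by_two_contingency(self):
        t = _partition(["a", "a", "b", "b"])
        p = _partition(["a", "b", "a", "b"])
        expected = pair_counting_ari(["a", "a", "b", "b"], ["a", "b", "a", "b"])
        assert ari(t, p) == pytest.approx(expected, abs=1e-12)
        assert adjusted_rand_score([0, 0, 1, 1], [0, 1, 0, 1]) == \
            pytest.approx(expected)

    def test_adjusted_for_chance(self):
        truth = _partition([0] * 50 + [1] * 50)
        vals = []
        for seed in range(200):
            labels = np.random.default_rng(seed).integers(0, 2, size=100)
            vals.append(ari(truth, _partition(labels)))
        assert abs(np.mean(vals)) < 0.05

    def test_matches_brute_force_pair_counting(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            a = rng.integers(0, 3, size=16).tolist()
            b = rng.integers(0, 4, size=16).tolist()
            assert ari(_partition(a), _partition(b)) == pytest.approx(
                pair_counting_ari(a, b), abs=1e-12)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(seed=st.integers(0, 1000))
def test_symmetry_and_permutation_invariance(seed):
    rng = np.random.default_rng(seed)
    a = rng.integers(0, 4, size=30)
    b = rng.integers(0, 3, size=30)
    pa, pb = _partition(a), _partition(b)
    assert nmi(pa, pb) == pytest.approx(nmi(pb, pa), abs=1e-12)
    assert ari(pa, pb) == pytest.approx(ari(pb, pa), abs=1e-12)
    # relabel: apply a random permutation to the label alphabet
    perm = rng.permutation(4)
    pa2 = _partition([f"L{perm[x]}" for x in a])
    assert nmi(pa2, pb) == pytest.approx(nmi(pa, pb), abs=1e-12)
    assert ari(pa2, pb) == pytest.approx(ari(pa, pb), abs=1e-12)


class TestModularity:
    def test_one_community_is_exactly_zero(self, two_triangles):
        G, _ = two_triangles
        P = _partition([0] * 6, ids=list(G.node_ids))
        assert modularity(G, P) == pytest.approx(0.0, abs=1e-15)

    def test_two_disjoint_triangles_score_half(self, two_triangles):
        G, P = two_triangles
        assert modularity(G, P) == pytest.approx(0.5, abs=1e-12)

    def test_all_singletons_closed_form(self, sbm3):
        G, _ = sbm3
        P = _partition(list(range(G.n_nodes)), ids=list(G.node_ids))
        _, degrees, vol = G.adjacency()
        m = vol / 2
        expected = -float((degrees ** 2).sum()) / (4 * m * m)
        assert modularity(G, P) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_aggregation_equals_double_sum(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        edges = [(f"n{i}", f"n{j}", float(rng.uniform(0.5, 2)))
                 for i in range(n) for j in range(i + 1, n)
                 if rng.random() < 0.15]
        G = Graph.from_edges(edges)
        labels = rng.integers(0, 4, size=G.n_nodes).tolist()
        P = _partition(labels, ids=list(G.node_ids))
        A = G.adjacency()[0].toarray()
        assert modularity(G, P) == pytest.approx(
            double_sum_modularity(A, labels), abs=1e-12)

    def test_bounded_above_by_one(self, sbm3):
        G, truth = sbm3
        assert modularity(G, truth) <= 1.0

    def test_uncovered_node_rejected(self, two_triangles):
        G, _ = two_triangles
        P = _partition([0] * 5, ids=list(G.node_ids)[:5])
        with pytest.raises(ValueError, match="cover"):
            modularity(G, P)
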