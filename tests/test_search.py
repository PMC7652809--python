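"""Candidate-k grids, mini-batch k-means wrapper, coarse/fine search and the
full detection pipeline."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scdkit import (SCDConfig, coarse_search, fine_search, gamma_estimate,
                    minibatch_kmeans, nmi, scd_detect, valid_range)
from scdkit.search import embedding_grid
from scdkit.synthetic import SBMSpec, generate_sbm

from oracles import exhaustive_best_k


class TestValidRange:
    def test_every_tenth_with_endpoint_appended(self):
        assert valid_range(5, 50, 10) == [5, 15, 25, 35, 45, 50]

    def test_degenerate_single_value(self):
        assert valid_range(5, 5, 10) == [5]

    def test_auto_gamma_thousand(self):
        g = gamma_estimate(1000)
        assert g == 100
        assert valid_range(2, 1000, g) == list(range(2, 1000, 100)) + [1000]

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(k_min=st.integers(2, 50), span=st.integers(0, 500),
           gamma=st.integers(1, 60))
    def test_grid_properties(self, k_min, span, gamma):
        K = k_min + span
        ks = valid_range(k_min, K, gamma)
        assert ks[0] == k_min and ks[-1] == K
        assert ks == sorted(set(ks))
        assert all(k_min <= k <= K for k in ks)


class TestGammaEstimate:
    @pytest.mark.parametrize("K,expected", [(1000, 100), (8, 4), (100, 22),
                                            (1, 1), (27, 9)])
    def test_cube_root_of_k_squared(self, K, expected):
        assert gamma_estimate(K) == expected

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(K=st.integers(1, 100_000))
    def test_bounds(self, K):
        g = gamma_estimate(K)
        assert 1 <= g
        assert g - 1 < K ** (2 / 3) <= g + 1e-6


class TestMiniBatchKMeans:
    def test_repeated_points_reach_global_optimum(self):
        pts = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
        X = np.repeat(pts, 10, axis=0)
        labels, centers = minibatch_kmeans(X, 3, seed=0)
        assert len(set(labels.tolist())) == 3
        # zero within-cluster scatter: each repeat group is one cluster
        for g in range(3):
            group = labels[g * 10:(g + 1) * 10]
            assert len(set(group.tolist())) == 1

    def test_k_equals_one_center_is_column_mean(self):
        X = np.random.default_rng(0).normal(size=(40, 3))
        labels, centers = minibatch_kmeans(X, 1, seed=0)
        assert set(labels.tolist()) == {0}
        np.testing.assert_allclose(centers[0], X.mean(axis=0), atol=1e-12)

    def test_two_separated_blobs_recovered(self, blob_embedding):
        X, truth = blob_embedding(2, per_blob=100, d=3, sep=10, sigma=0.1,
                                  seed=3)
        labels, _ = minibatch_kmeans(X, 2, seed=1)
        agree = (labels == truth).mean()
        assert agree in (0.0, 1.0)  # exact up to label swap

    def test_k_beyond_distinct_rows_warns_and_shrinks(self):
        X = np.repeat(np.array([[0.0], [1.0]]), 5, axis=0)
        with pytest.warns(UserWarning, match="distinct rows"):
            labels, _ = minibatch_kmeans(X, 4, seed=0)
        assert len(set(labels.tolist())) == 2


class TestCoarseSearch:
    def test_finds_planted_blob_count(self, blob_embedding):
        X, _ = blob_embedding(4, per_blob=25, seed=1)
        config = SCDConfig(k_min=2, K=10, gamma=1, w=10,
                           seed=0, embedding_grid=[{"method": "netmf"}])
        trace = coarse_search(X, config)

        def cluster(X_, k):
            return minibatch_kmeans(X_, k, seed=0)[0]

        k_star, _ = exhaustive_best_k(X, range(2, 11), cluster)
        assert trace.best_k == k_star == 4

    def test_stopping_window_one_halts_after_two(self, blob_embedding):
        X, _ = blob_embedding(2, per_blob=30, seed=2)
        config = SCDConfig(k_min=2, K=10, gamma=1, w=1, seed=0)
        trace = coarse_search(X, config)
        assert len(trace.evaluations) == 2
        assert trace.best_k == 2

    def test_exhaustive_trace_contains_coarser_traces(self, blob_embedding):
        X, _ = blob_embedding(3, per_blob=20, seed=4)
        base = dict(k_min=2, K=12, w=100, seed=0)
        exhaustive = {e.k for e in
                      coarse_search(X, SCDConfig(gamma=1, **base)).evaluations}
        sparse = {e.k for e in
                  coarse_search(X, SCDConfig(gamma=3, **base)).evaluations}
        assert sparse <= exhaustive


class TestFineSearch:
    def test_refines_to_true_optimum_between_grid_points(self, blob_embedding):
        X, _ = blob_embedding(7, per_blob=20, seed=5)
        config = SCDConfig(k_min=5, K=15, gamma=10, w=10, seed=0)
        coarse = coarse_search(X, config)
        assert coarse.best_k in (5, 15)
        merged = fine_search(X, config, coarse.best_k, trace=coarse)
        assert merged.best_k == 7

    def test_fine_best_never_below_coarse_best(self, blob_embedding):
        for seed in range(4):
            X, _ = blob_embedding(4, per_blob=15, seed=seed)
            config = SCDConfig(k_min=2, K=12, gamma=4, w=5, seed=0)
            coarse = coarse_search(X, config)
            coarse_best = coarse.best_silhouette
            merged = fine_search(X, config, coarse.best_k, trace=coarse)
            assert merged.best_silhouette >= coarse_best

    def test_gamma_one_adds_at_most_two_evaluations(self, blob_embedding):
        X, _ = blob_embedding(3, per_blob=20, seed=6)
        config = SCDConfig(k_min=2, K=10, gamma=1, w=5, seed=0)
        coarse = coarse_search(X, config)
        n_coarse = len(coarse.evaluations)
        merged = fine_search(X, config, coarse.best_k, trace=coarse)
        assert len(merged.evaluations) - n_coarse <= 2


class TestSCDDetect:
    CONFIG = dict(k_min=2, K=10, gamma=1, w=5,
                  embedding_grid=[{"method": "netmf", "T": 3, "b": 1, "d": 16}])

    def test_recovers_planted_sbm_partition(self, sbm3):
        G, truth = sbm3
        partition, trace = scd_detect(G, SCDConfig(seed=5, **self.CONFIG))
        assert partition.k == 3
        assert nmi(truth, partition) == pytest.approx(1.0)
        assert all(-1 <= e.silhouette <= 1 for e in trace.evaluations)

    def test_duplicate_grid_settings_are_deduplicated(self, sbm3):
        G, _ = sbm3
        cfg = dict(self.CONFIG)
        cfg["embedding_grid"] = cfg["embedding_grid"] * 3
        p1, t1 = scd_detect(G, SCDConfig(seed=5, **cfg))
        p2, t2 = scd_detect(G, SCDConfig(seed=5, **self.CONFIG))
        assert p1 == p2
        assert len(t1.evaluations) == len(t2.evaluations)

    def test_same_seed_reproduces_partition(self, sbm3):
        G, _ = sbm3
        p1, _ = scd_detect(G, SCDConfig(seed=9, **self.CONFIG))
        p2, _ = scd_detect(G, SCDConfig(seed=9, **self.CONFIG))
        assert p1 == p2

    def test_exhaustive_gamma_dominates(self, sbm3):
        G, _ = sbm3
        base = dict(self.CONFIG)
        del base["gamma"]
        _, t1 = scd_detect(G, SCDConfig(seed=5, gamma=1, **base))
        for gamma in (2, 4):
            _, tg = scd_detect(G, SCDConfig(seed=5, gamma=gamma, **base))
            assert t1.best_silhouette >= tg.best_silhouette - 1e-12

    def test_empty_grid_rejected(self, sbm3):
        G, _ = sbm3
        with pytest.raises(ValueError, match="grid"):
            scd_detect(G, SCDConfig(embedding_grid=[]))

    def test_grid_presets(self):
        assert len(embedding_grid("full")) == 90
        assert 1 <= len(embedding_grid("fast")) < 10
        with pytest.raises(ValueError):
            embedding_grid("nope")
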