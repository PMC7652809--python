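from __future__ import annotations

import numpy as np
import pytest

from scdkit import Graph, Partition
from scdkit.synthetic import SBMSpec, generate_sbm


@pytest.fixture
def single_edge() -> Graph:
    return Graph.from_edges([("a", "b", 1.0)])


@pytest.fixture
def triangle() -> Graph:
    return Graph.from_edges(
        [("a", "b", 1.0), ("b", "c", 1.0), ("a", "c", 1.0)]
    )


@pytest.fixture
def two_triangles() -> tuple[Graph, Partition]:
    G = Graph.from_edges(
        [("a", "b", 1.0), ("b", "c", 1.0), ("a", "c", 1.0),
         ("d", "e", 1.0), ("e", "f", 1.0), ("d", "f", 1.0)]
    )
    P = Partition(node_ids=list(G.node_ids), labels=[0, 0, 0, 1, 1, 1])
    return G, P


@pytest.fixture
def sbm3() -> tuple[Graph, Partition]:
    """Three 30-node blocks, p_in=0.9 / p_out=0.02: an easy planted partition."""
    return generate_sbm(SBMSpec(block_sizes=(30, 30, 30),
                                p_in=0.9, p_out=0.02, seed=11))


@pytest.fixture
def blob_embedding():
    """Embedding-like point cloud with a planted number of blobs."""

    def make(n_blobs: int, per_blob: int = 25, d: int = 4, sep: float = 10.0,
             sigma: float = 0.3, seed: int = 0):
        rng = np.random.default_rng(seed)
        centers = rng.normal(scale=sep, size=(n_blobs, d))
        X = np.vstack([
            centers[b] + rng.normal(scale=sigma, size=(per_blob, d))
            for b in range(n_blobs)
        ])
        labels = np.repeat(np.arange(n_blobs), per_blob)
        return X, labels

    return make
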