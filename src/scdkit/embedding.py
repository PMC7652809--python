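"""Embedding matrix container shared by the NetMF and PPR embedders."""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np


@dataclass
class EmbeddingMatrix:
    """|N| x d real matrix; row i is the embedding of internal node i.

    ``provenance`` records which embedder and parameters produced the matrix
    so downstream results are reproducible from the sidecar alone.
    """

    values: np.ndarray
    node_ids: list[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("embedding must be a 2-D matrix")
        if self.values.shape[0] != len(self.node_ids):
            raise ValueError("row count must equal the number of nodes")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("embedding contains non-finite entries")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]

    def save(self, prefix) -> None:
        """Persist as ``<prefix>.emb.tsv`` plus a ``<prefix>.emb.json`` sidecar."""
        with open(f"{prefix}.emb.tsv", "w", encoding="utf-8") as fh:
            for u, row in zip(self.node_ids, self.values):
                fh.write(u + "\t" + "\t".join(f"{x:.10g}" for x in row) + "\n")
        with open(f"{prefix}.emb.json", "w", encoding="utf-8") as fh:
            json.dump(self.provenance, fh, indent=2, sort_keys=True)

    @classmethod
    def load(cls, prefix) -> "EmbeddingMatrix":
        node_ids: list[str] = []
        rows: list[list[float]] = []
        with open(f"{prefix}.emb.tsv", encoding="utf-8") as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                node_ids.append(parts[0])
                rows.append([float(x) for x in parts[1:]])
        try:
            with open(f"{prefix}.emb.json", encoding="utf-8") as fh:
                prov = json.load(fh)
        except FileNotFoundError:
            prov = {}
        return cls(values=np.array(rows), node_ids=node_ids, provenance=prov)
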