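"""Undirected weighted graph container and plain-text I/O.

The graph model is deliberately small: a list of external node identifiers
(strings), a dictionary of undirected edges keyed by internal index pairs
``(i, j)`` with ``i < j``, and positive real weights.  Unweighted networks are
weighted networks with all weights equal to 1.  Internal indices are
contiguous ``0..n_nodes-1`` and bijective with ``node_ids``.

Edge lists follow the SNAP dialect: one whitespace-separated ``u v [w]`` per
line, lines starting with ``#`` ignored.  Community memberships are two-column
TSV ``node_id<TAB>label`` with labels preserved verbatim.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import scipy.sparse as sp

from .partition import Partition

logger = logging.getLogger(__name__)

__all__ = [
    "Graph",
    "read_edgelist",
    "write_edgelist",
    "adjacency",
    "read_membership",
    "write_membership",
]


@dataclass
class Graph:
    """Undirected weighted network with a preserved external-ID map.

    Attributes
    ----------
    node_ids
        External node identifiers; position is the internal index.
    edges
        ``{(i, j): w}`` with ``i < j`` and ``w > 0``.
    """

    node_ids: list[str]
    edges: dict[tuple[int, int], float]
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {v: i for i, v in enumerate(self.node_ids)}
        if len(self._index) != len(self.node_ids):
            raise ValueError("duplicate node identifiers")
        n = len(self.node_ids)
        for (i, j), w in self.edges.items():
            if not (0 <= i < j < n):
                raise ValueError(f"invalid edge index pair {(i, j)}")
            if not w > 0:
                raise ValueError(f"non-positive weight {w} on edge {(i, j)}")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def index_of(self, node_id: str) -> int:
        return self._index[node_id]

    def adjacency(self) -> tuple[sp.csr_matrix, np.ndarray, float]:
        """Sparse symmetric adjacency, generalized degrees, and volume.

        Returns ``(A, d, vol)`` where ``d_i = sum_j A_ij`` and
        ``vol = sum_ij A_ij``, i.e. twice the total edge weight.
        """
        n = self.n_nodes
        if self.n_edges == 0:
            A = sp.csr_matrix((n, n))
        else:
            ij = np.array(list(self.edges.keys()), dtype=np.int64)
            w = np.array(list(self.edges.values()), dtype=np.float64)
            rows = np.concatenate([ij[:, 0], ij[:, 1]])
            cols = np.concatenate([ij[:, 1], ij[:, 0]])
            data = np.concatenate([w, w])
            A = sp.coo_matrix((data, (rows, cols)), shape=(n, n)).tocsr()
        degrees = np.asarray(A.sum(axis=1)).ravel()
        vol = float(degrees.sum())
        return A, degrees, vol

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_weighted_edges_from((i, j, w) for (i, j), w in self.edges.items())
        return g

    @classmethod
    def from_edges(
        cls,
        edges: list[tuple[str, str, float]],
        nodes: list[str] | None = None,
    ) -> "Graph":
        """Build a graph from ``(u, v, w)`` triples with external IDs.

        The node universe is the set of edge endpoints in first-seen order,
        optionally extended by an explicit node list (admitting isolated
        nodes).  Duplicate undirected edges keep the last weight; self-loops
        are dropped.  Both events are logged as warnings.
        """
        ids: list[str] = []
        index: dict[str, int] = {}
        if nodes is not None:
            for u in nodes:
                if u not in index:
                    index[u] = len(ids)
                    ids.append(u)

        def idx(u: str) -> int:
            if u not in index:
                index[u] = len(ids)
                ids.append(u)
            return index[u]

        edge_map: dict[tuple[int, int], float] = {}
        for u, v, w in edges:
            if u == v:
                logger.warning("dropping self-loop on node %r", u)
                continue
            i, j = idx(u), idx(v)
            key = (i, j) if i < j else (j, i)
            if key in edge_map:
                logger.warning(
                    "duplicate edge %r-%r: keeping last weight %g", u, v, w
                )
            edge_map[key] = float(w)
        return cls(node_ids=ids, edges=edge_map)


def read_edgelist(
    path, weighted: bool = False, nodes_path=None
) -> Graph:
    """Read a whitespace-separated edge list into a :class:`Graph`.

    Parameters
    ----------
    path
        File with one ``u v [w]`` edge per line; ``#`` lines are comments.
    weighted
        When true, a third column is parsed as a positive real weight
        (missing third column means weight 1).  When false any third column
        is rejected as malformed.
    nodes_path
        Optional file with one node ID per line, admitting isolated nodes.

    Raises
    ------
    ValueError
        On an empty file, a malformed line, or a non-positive weight; the
        message names the offending line number.
    """
    triples: list[tuple[str, str, float]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) == 2:
                u, v = parts
                w = 1.0
            elif len(parts) == 3 and weighted:
                u, v = parts[:2]
                try:
                    w = float(parts[2])
                except ValueError as exc:
                    raise ValueError(
                        f"{path}:{lineno}: unparseable weight {parts[2]!r}"
                    ) from exc
                if not np.isfinite(w) or w <= 0:
                    raise ValueError(
                        f"{path}:{lineno}: non-positive weight {parts[2]!r}"
                    )
            else:
                raise ValueError(
                    f"{path}:{lineno}: malformed line {line!r} "
                    f"(expected 'u v'{' or u v w' if weighted else ''})"
                )
            triples.append((u, v, w))

    nodes = None
    if nodes_path is not None:
        with open(nodes_path, encoding="utf-8") as fh:
            nodes = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]

    if not triples and not nodes:
        raise ValueError(f"{path}: empty edge list")
    return Graph.from_edges(triples, nodes=nodes)


def write_edgelist(G: Graph, path, weighted: bool = True) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for (i, j), w in sorted(G.edges.items()):
            u, v = G.node_ids[i], G.node_ids[j]
            if weighted:
                fh.write(f"{u} {v} {w:g}\n")
            else:
                fh.write(f"{u} {v}\n")


def adjacency(G: Graph) -> tuple[sp.csr_matrix, np.ndarray, float]:
    """Module-level alias for :meth:`Graph.adjacency`."""
    return G.adjacency()


def read_membership(path, graph: Graph | None = None) -> Partition:
    """Read a two-column TSV ``node_id<TAB>label`` membership file.

    Labels are preserved verbatim (no renaming).  When ``graph`` is given,
    the node sets must match exactly; offenders are listed in the error.
    """
    node_ids: list[str] = []
    labels: list[str] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: malformed line {line!r}")
            u, lab = parts
            if u in seen:
                raise ValueError(f"{path}:{lineno}: duplicate node {u!r}")
            seen.add(u)
            node_ids.append(u)
            labels.append(lab)
    if not node_ids:
        raise ValueError(f"{path}: empty membership file")
    part = Partition(node_ids=node_ids, labels=labels)
    if graph is not None:
        unknown = sorted(set(node_ids) - set(graph.node_ids))
        if unknown:
            raise ValueError(
                f"{path}: nodes absent from the graph: {unknown[:10]}"
                + ("..." if len(unknown) > 10 else "")
            )
        missing = sorted(set(graph.node_ids) - set(node_ids))
        if missing:
            raise ValueError(
                f"{path}: graph nodes missing a label: {missing[:10]}"
                + ("..." if len(missing) > 10 else "")
            )
    return part


def write_membership(P: Partition, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for u, lab in zip(P.node_ids, P.labels):
            fh.write(f"{u}\t{lab}\n")
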