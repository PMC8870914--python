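"""Simple directed graphs: the shared in-memory container.

Vertices are indexed ``0 .. n-1`` internally; the on-disk edge-list format
(see :mod:`randomplots.graphio`) is 1-based to match the usual presentation.
Edges are ordered pairs ``(source, destination)``.  Loops and duplicate
ordered pairs are rejected at construction time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx
import numpy as np
import scipy.sparse as sp


@dataclass(frozen=True)
class SimpleDigraph:
    """A simple digraph: ``n`` vertices and a set of ordered edges.

    Parameters
    ----------
    n
        Number of vertices.
    edges
        Set of ``(source, destination)`` pairs with 0-based vertex indices.
        No loops, no duplicates (enforced).
    """

    n: int
    edges: frozenset[tuple[int, int]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError(f"vertex count must be non-negative, got {self.n}")
        if not isinstance(self.edges, frozenset):
            object.__setattr__(self, "edges", frozenset(self.edges))
        for u, v in self.edges:
            if u == v:
                raise ValueError(f"loop ({u}, {v}) is not allowed in a simple digraph")
            if not (0 <= u < self.n and 0 <= v < self.n):
                raise ValueError(f"edge ({u}, {v}) out of range for n={self.n}")

    @classmethod
    def from_edges(cls, n: int, edges: Iterable[tuple[int, int]]) -> "SimpleDigraph":
        edge_list = [(int(u), int(v)) for u, v in edges]
        edge_set = frozenset(edge_list)
        if len(edge_set) != len(edge_list):
            raise ValueError("duplicate ordered edges are not allowed in a simple digraph")
        return cls(n, edge_set)

    @classmethod
    def from_adjacency(cls, adjacency: np.ndarray) -> "SimpleDigraph":
        """Build from a boolean adjacency matrix (rows = sources). The diagonal is ignored."""
        adjacency = np.asarray(adjacency, dtype=bool)
        n = adjacency.shape[0]
        if adjacency.shape != (n, n):
            raise ValueError("adjacency matrix must be square")
        a = adjacency.copy()
        np.fill_diagonal(a, False)
        us, vs = np.nonzero(a)
        return cls(n, frozenset(zip(us.tolist(), vs.tolist())))

    @property
    def num_edges(self) -> int:
        return len(self.edges)

    def in_degrees(self) -> np.ndarray:
        deg = np.zeros(self.n, dtype=np.int64)
        for _, v in self.edges:
            deg[v] += 1
        return deg

    def out_degrees(self) -> np.ndarray:
        deg = np.zeros(self.n, dtype=np.int64)
        for u, _ in self.edges:
            deg[u] += 1
        return deg

    def to_adjacency(self) -> np.ndarray:
        """Dense boolean adjacency matrix, rows = sources, columns = destinations."""
        a = np.zeros((self.n, self.n), dtype=bool)
        for u, v in self.edges:
            a[u, v] = True
        return a

    def to_sparse(self) -> sp.csr_matrix:
        """CSR adjacency with unit weights (rows = sources)."""
        if not self.edges:
            return sp.csr_matrix((self.n, self.n), dtype=np.int8)
        us, vs = zip(*self.edges)
        data = np.ones(len(us), dtype=np.int8)
        return sp.csr_matrix((data, (us, vs)), shape=(self.n, self.n))

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(range(self.n))
        g.add_edges_from(self.edges)
        return g

    @classmethod
    def from_networkx(cls, g: nx.DiGraph) -> "SimpleDigraph":
        nodes = sorted(g.nodes())
        index = {v: i for i, v in enumerate(nodes)}
        return cls.from_edges(len(nodes), ((index[u], index[v]) for u, v in g.edges()))
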