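"""Reading and writing graphs: plain edge lists and GraphML.

The canonical on-disk format is a plain-text edge list: one directed edge
per line as two whitespace-separated 1-based vertex indices, with ``#``
comment lines ignored.  A ``# n=<N>`` header declares the vertex count
(needed for graphs with trailing isolated vertices, or empty graphs).
GraphML export/import goes through networkx for interchange with other
tools.
"""

from __future__ import annotations

import re
from pathlib import Path

import networkx as nx

from randomplots.digraph import SimpleDigraph

_HEADER_RE = re.compile(r"#\s*n\s*=\s*(\d+)")


class EdgeListError(ValueError):
    """Malformed edge-list input, reported with its line number."""


def write_edge_list(g: SimpleDigraph, path: str | Path) -> None:
    """Write ``g`` as a 1-based edge list with a ``# n=`` header."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# n={g.n}\n")
        for u, v in sorted(g.edges):
            fh.write(f"{u + 1} {v + 1}\n")


def read_edge_list(path: str | Path) -> SimpleDigraph:
    """Parse a 1-based edge list, enforcing simplicity.

    Loops, duplicate edges and malformed lines raise :class:`EdgeListError`
    naming the offending line.  Without a ``# n=`` header the vertex count
    is the largest index seen.
    """
    path = Path(path)
    n_declared: int | None = None
    edges: set[tuple[int, int]] = set()
    max_index = 0
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                match = _HEADER_RE.match(line)
                if match:
                    n_declared = int(match.group(1))
                continue
            parts = line.split()
            if len(parts) != 2:
                raise EdgeListError(f"{path}:{lineno}: expected two vertex indices, got {line!r}")
            try:
                u, v = int(parts[0]), int(parts[1])
            except ValueError as exc:
                raise EdgeListError(f"{path}:{lineno}: non-integer vertex index in {line!r}") from exc
            if u < 1 or v < 1:
                raise EdgeListError(f"{path}:{lineno}: vertex indices are 1-based, got {line!r}")
            if u == v:
                raise EdgeListError(f"{path}:{lineno}: loop edge {u} -> {v} is not allowed")
            edge = (u - 1, v - 1)
            if edge in edges:
                raise EdgeListError(f"{path}:{lineno}: duplicate edge {u} -> {v}")
            edges.add(edge)
            max_index = max(max_index, u, v)
    n = n_declared if n_declared is not None else max_index
    if max_index > n:
        raise EdgeListError(f"{path}: vertex index {max_index} exceeds declared n={n}")
    return SimpleDigraph(n, frozenset(edges))


def write_graphml(g: SimpleDigraph, path: str | Path) -> None:
    nx.write_graphml(g.to_networkx(), str(path))


def read_graphml(path: str | Path) -> SimpleDigraph:
    return SimpleDigraph.from_networkx(nx.read_graphml(str(path), node_type=int))
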