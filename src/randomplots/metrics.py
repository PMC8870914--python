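"""Scalar diversity metrics of a simple digraph.

Seven structural properties plus density, each chosen to (a) be meaningful
for *directed* graphs and (b) be defined for (almost) arbitrary digraphs, so
that whole generator ensembles can be scored.  Metrics that are undefined on
a particular graph (reciprocity of an edgeless graph, transitivity without
open wedges, non-convergent eigenvector centrality) are reported as ``None``
rather than 0, so ensemble clouds are not distorted.

Standard graph algorithms are delegated to networkx; the walk-based
bipartivity measure is computed directly from dense matrix exponentials of
the (possibly asymmetric) adjacency matrix, which is exact but O(N^3) - fine
up to a few thousand vertices.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import scipy.linalg

from randomplots.digraph import SimpleDigraph


@dataclass(frozen=True)
class MetricRecord:
    """Density plus the seven scalar properties of one digraph.

    ``None`` marks a metric undefined for this graph.
    """

    graph_id: str
    density: float
    avg_reachability: float
    largest_scc: int
    spectral_bipartivity: float
    reciprocity: float | None
    transitivity: float | None
    avg_clustering: float
    avg_eigenvector_centrality: float | None

    @classmethod
    def field_names(cls) -> tuple[str, ...]:
        return tuple(cls.__dataclass_fields__)


METRIC_NAMES = (
    "density",
    "avg_reachability",
    "largest_scc",
    "spectral_bipartivity",
    "reciprocity",
    "transitivity",
    "avg_clustering",
    "avg_eigenvector_centrality",
)


def density(g: SimpleDigraph) -> float:
    """``|E| / (N(N-1))``: the filled fraction of possible ordered pairs."""
    if g.n < 2:
        raise ValueError("density needs at least 2 vertices")
    return g.num_edges / (g.n * (g.n - 1))


def avg_reachability(g: SimpleDigraph) -> float:
    """Mean over vertices of the fraction of *other* vertices reachable by a
    directed path (the vertex itself is excluded from both sides)."""
    if g.n < 2:
        raise ValueError("average reachability needs at least 2 vertices")
    dg = g.to_networkx()
    total = sum(len(nx.descendants(dg, v)) for v in dg)
    return total / (g.n * (g.n - 1))


def largest_scc_size(g: SimpleDigraph) -> int:
    """Size of the largest strongly connected component (>= 1 for N >= 1)."""
    if g.n < 1:
        raise ValueError("graph must have at least one vertex")
    return max(len(c) for c in nx.strongly_connected_components(g.to_networkx()))


def spectral_bipartivity(g: SimpleDigraph) -> float:
    """Even-closed-walk weight over total closed-walk weight.

    ``trace(cosh(A)) / trace(exp(A))`` with ``A`` the adjacency matrix taken
    as-is (asymmetric for digraphs; the matrix-function formula extends
    directly).  Equals 1 for bipartite or walk-free structures and decreases
    as odd closed walks appear.
    """
    if g.n < 1:
        raise ValueError("graph must have at least one vertex")
    a = g.to_adjacency().astype(np.float64)
    exp_pos = scipy.linalg.expm(a)
    exp_neg = scipy.linalg.expm(-a)
    return float(0.5 * np.trace(exp_pos + exp_neg) / np.trace(exp_pos))


def reciprocity(g: SimpleDigraph) -> float | None:
    """Fraction of edges whose reverse edge also exists; ``None`` if edgeless."""
    if g.num_edges == 0:
        return None
    mutual = sum(1 for u, v in g.edges if (v, u) in g.edges)
    return mutual / g.num_edges


def transitivity(g: SimpleDigraph) -> float | None:
    """Fraction of open directed wedges closed by a chord.

    Over ordered triples of distinct vertices with ``(u,v)`` and ``(v,w)``
    present, the fraction that also have ``(u,w)``.  Counted via the
    adjacency matrix: wedges are off-diagonal entries of ``A^2``; closed
    wedges additionally require ``A[u,w]``.  ``None`` if no open wedge.
    """
    if g.n < 3:
        raise ValueError("transitivity needs at least 3 vertices")
    a = g.to_adjacency().astype(np.int64)
    a2 = a @ a
    wedges = int(a2.sum() - np.trace(a2))
    if wedges == 0:
        return None
    closed = int((a2 * a).sum())  # diag(A) = 0, so u != w automatically
    return closed / wedges


def avg_clustering(g: SimpleDigraph) -> float:
    """Vertex-averaged directed clustering coefficient (Fagiolo's
    generalization, as implemented by networkx); vertices with fewer than
    two neighbours contribute 0."""
    if g.n < 1:
        raise ValueError("graph must have at least one vertex")
    return float(nx.average_clustering(g.to_networkx()))


def avg_eigenvector_centrality(
    g: SimpleDigraph, tol: float = 1e-6, max_iter: int = 1000
) -> float | None:
    """Mean entry of the principal eigenvector accumulated along in-edges.

    Power iteration with L2 normalization; a vertex is important when
    important vertices point at it.  Returns ``None`` when the iteration
    does not converge (e.g. on a DAG, whose adjacency matrix is nilpotent).
    """
    if g.n < 1:
        raise ValueError("graph must have at least one vertex")
    try:
        scores = nx.eigenvector_centrality(g.to_networkx(), tol=tol, max_iter=max_iter)
    except nx.PowerIterationFailedConvergence:
        return None
    return float(np.mean(list(scores.values())))


def compute_all(g: SimpleDigraph, graph_id: str = "") -> MetricRecord:
    """All eight scalar properties of one digraph."""
    return MetricRecord(
        graph_id=graph_id,
        density=density(g),
        avg_reachability=avg_reachability(g),
        largest_scc=largest_scc_size(g),
        spectral_bipartivity=spectral_bipartivity(g),
        reciprocity=reciprocity(g),
        transitivity=transitivity(g),
        avg_clustering=avg_clustering(g),
        avg_eigenvector_centrality=avg_eigenvector_centrality(g),
    )


def compute(g: SimpleDigraph, name: str):
    """One named metric of one digraph (see ``METRIC_NAMES``)."""
    if name not in METRIC_NAMES:
        raise ValueError(f"unknown metric {name!r}; choose from {METRIC_NAMES}")
    func = {
        "density": density,
        "avg_reachability": avg_reachability,
        "largest_scc": largest_scc_size,
        "spectral_bipartivity": spectral_bipartivity,
        "reciprocity": reciprocity,
        "transitivity": transitivity,
        "avg_clustering": avg_clustering,
        "avg_eigenvector_centrality": avg_eigenvector_centrality,
    }[name]
    return func(g)
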