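"""Stochastic synthesis of a simple digraph matching a reference plot pair.

Edges are added one at a time until the target edge count ``D`` (the common
degree sum of the reference pair) is reached.  At each step a fair coin
decides whether the indegree side or the outdegree side is processed first;
the first endpoint is drawn among vertices that still have at least one
admissible partner, with probability proportional to its target degree, and
the partner is then drawn among admissible vertices with probability
proportional to its own target degree on the opposite side.  Loops and
duplicate ordered edges are never created, so the result is simple with
exactly ``D`` edges.

Selection probabilities follow the sequential configuration-model scheme:
each vertex's weight is its *remaining* target capacity (target degree
minus current degree), so vertices stop attracting edges once their target
is met and feasible targets are realized essentially exactly.  When every
admissible vertex has exhausted its capacity - which is bound to happen for
unrealizable target pairs, since the loop must still reach ``D`` edges -
the choice falls back to uniform over the admissible set.  Steep references
that hug the ceiling of ``N - 1`` partners are exactly the hard-to-realize
ones, so their forced shortfalls concentrate at the top of the plot while
the fallback spreads surplus edges over low-target vertices: the actual
plot comes out "smoothed" relative to a steep reference, which the L1
accuracy metrics quantify.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx
import numpy as np

from randomplots.digraph import SimpleDigraph
from randomplots.rvdp import ReferencePlotPair

#: Exhaustive-search budget of :func:`is_realizable`.
MAX_EXHAUSTIVE_N = 7


@dataclass(frozen=True)
class BuildResult:
    """A synthesized digraph with its reference targets and L1 errors.

    ``sigma`` maps each vertex ``i`` to the index of its outdegree target:
    vertex ``i`` aims for indegree ``d_minus[i]`` and outdegree
    ``d_plus[sigma[i]]``.  ``l_minus``/``l_plus`` are the normalized L1
    deviations of the realized degrees from those targets, both in [0, 1].
    """

    graph: SimpleDigraph
    sigma: np.ndarray
    reference: ReferencePlotPair
    l_minus: float
    l_plus: float


def _or_uniform(weights: np.ndarray, admissible: np.ndarray) -> np.ndarray:
    """``weights`` unless they carry no mass, then uniform over ``admissible``."""
    return weights if weights.any() else admissible.astype(np.float64)


def _weighted_pick(weights: np.ndarray, u: float) -> int:
    """Index drawn proportionally to nonnegative ``weights`` using uniform ``u``."""
    cum = np.cumsum(weights)
    total = cum[-1]
    if total <= 0:
        raise RuntimeError("no admissible vertex with positive weight")
    return int(min(np.searchsorted(cum, u * total, side="right"), weights.size - 1))


def build(
    reference: ReferencePlotPair,
    rng: np.random.Generator,
    sigma: np.ndarray | None = None,
) -> BuildResult:
    """Synthesize a simple digraph whose degree plots track ``reference``.

    ``sigma`` decouples each vertex's outdegree target from its indegree
    target (both reference arrays are sorted, so without shuffling the two
    targets would be strongly positively correlated).  If not supplied it is
    drawn uniformly from the given generator.
    """
    n = reference.n
    d = reference.total_degree
    if sigma is None:
        sigma = rng.permutation(n)
    else:
        sigma = np.asarray(sigma, dtype=np.int64)
        if sorted(sigma.tolist()) != list(range(n)):
            raise ValueError("sigma must be a permutation of 0..N-1")

    target_in = reference.d_minus.astype(np.int64)  # indegree targets by vertex
    target_out = reference.d_plus[sigma].astype(np.int64)  # outdegree targets by vertex

    # Diagonal marked used so loop exclusion rides along with duplicate exclusion;
    # row/col "used" counts therefore saturate at N, not N-1.
    adj = np.zeros((n, n), dtype=bool)
    np.fill_diagonal(adj, True)
    row_used = np.ones(n, dtype=np.int64)
    col_used = np.ones(n, dtype=np.int64)

    # Remaining capacities, clipped at zero and updated in place.
    w_in = target_in.astype(np.float64)
    w_out = target_out.astype(np.float64)
    sides = rng.integers(0, 2, size=d)
    u1 = rng.random(d)
    u2 = rng.random(d)
    for t in range(d):
        if sides[t] == 0:  # indegree side first
            mask = col_used < n
            first = _weighted_pick(_or_uniform(w_in * mask, mask), u1[t])
            partners = ~adj[:, first]
            src = _weighted_pick(_or_uniform(w_out * partners, partners), u2[t])
            dst = first
        else:  # outdegree side first
            mask = row_used < n
            first = _weighted_pick(_or_uniform(w_out * mask, mask), u1[t])
            partners = ~adj[first, :]
            dst = _weighted_pick(_or_uniform(w_in * partners, partners), u2[t])
            src = first
        adj[src, dst] = True
        row_used[src] += 1
        col_used[dst] += 1
        if w_out[src] > 0:
            w_out[src] -= 1
        if w_in[dst] > 0:
            w_in[dst] -= 1

    graph = SimpleDigraph.from_adjacency(adj)
    l_minus, l_plus = l1_errors(graph, reference, sigma)
    return BuildResult(graph, sigma, reference, l_minus, l_plus)


def l1_errors(
    graph: SimpleDigraph, reference: ReferencePlotPair, sigma: np.ndarray
) -> tuple[float, float]:
    """Normalized L1 deviation of realized degrees from per-vertex targets.

    ``L- = sum_i |indeg(v_i) - D-(i)| / (N(N-1))`` and symmetrically for
    ``L+`` with the shuffled outdegree targets ``D+(sigma(i))``.  Both lie
    in [0, 1].
    """
    if graph.n != reference.n:
        raise ValueError("graph and reference must have the same vertex count")
    n = graph.n
    norm = n * (n - 1)
    l_minus = float(np.abs(graph.in_degrees() - reference.d_minus).sum()) / norm
    l_plus = float(np.abs(graph.out_degrees() - reference.d_plus[sigma]).sum()) / norm
    return l_minus, l_plus


def sorted_plot_errors(
    graph: SimpleDigraph, reference: ReferencePlotPair
) -> tuple[float, float]:
    """L1 errors between the *sorted* actual and reference degree plots.

    A companion to :func:`l1_errors` for plot-overlay comparisons: actual
    degrees are sorted ascending before differencing, so vertex identity
    (and the shuffle ``sigma``) plays no role.
    """
    n = graph.n
    norm = n * (n - 1)
    l_minus = float(np.abs(np.sort(graph.in_degrees()) - reference.d_minus).sum()) / norm
    l_plus = float(np.abs(np.sort(graph.out_degrees()) - reference.d_plus).sum()) / norm
    return l_minus, l_plus


def _pairing_feasible(in_deg: tuple[int, ...], out_deg: tuple[int, ...]) -> bool:
    """Can a simple digraph give vertex ``i`` indegree ``in_deg[i]`` and
    outdegree ``out_deg[i]``?  Checked as a unit-capacity bipartite flow with
    the diagonal (loop) arcs removed."""
    n = len(in_deg)
    total = sum(in_deg)
    g = nx.DiGraph()
    for i in range(n):
        if out_deg[i] > 0:
            g.add_edge("s", ("u", i), capacity=out_deg[i])
        if in_deg[i] > 0:
            g.add_edge(("v", i), "t", capacity=in_deg[i])
        for j in range(n):
            if i != j:
                g.add_edge(("u", i), ("v", j), capacity=1)
    if total == 0:
        return True
    flow_value, _ = nx.maximum_flow(g, "s", "t")
    return flow_value == total


def is_realizable(in_degrees, out_degrees) -> bool:
    """Whether a pair of degree multisets is weakly graphical (exhaustive).

    True iff *some* assignment of the outdegree values to the vertices
    carrying the given indegree values admits a simple digraph realizing
    both exactly.  All distinct assignments are enumerated, each checked by
    integer-flow feasibility, so the search is limited to ``N <= 7``.
    Multisets with unequal sums are unrealizable by definition.
    """
    a = tuple(int(x) for x in in_degrees)
    b = tuple(int(x) for x in out_degrees)
    if len(a) != len(b):
        raise ValueError("degree multisets must have equal length")
    n = len(a)
    if n > MAX_EXHAUSTIVE_N:
        raise ValueError(f"exhaustive search limited to N <= {MAX_EXHAUSTIVE_N}")
    if sum(a) != sum(b):
        return False
    if any(x < 0 or x > n - 1 for x in a + b):
        return False
    seen: set[tuple[int, ...]] = set()
    for perm in itertools.permutations(b):
        if perm in seen:
            continue
        seen.add(perm)
        if _pairing_feasible(a, perm):
            return True
    return False
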