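"""Directed baseline graph generators and their parameter-sampling schemes.

Three classical null models, in directed form, serve as comparison points
for the degree-plot-targeted generator: the Erdős–Rényi–Gilbert model (every
ordered pair an edge independently with probability ``pe``), a directed
Watts–Strogatz small-world model (reciprocal ring lattice with per-edge
rewiring), and a directed scale-free growth model with the usual
alpha/beta/gamma step mix.  ``sample_params`` draws one parameter set per
graph so that an ensemble sweeps each model's reachable region of density.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from randomplots.digraph import SimpleDigraph

#: Preferential-attachment smoothing constants: added to the in-/outdegree of
#: every candidate so zero-degree vertices remain selectable.
DELTA_IN = 0.2
DELTA_OUT = 0.0

#: Attempts to re-propose a rejected (loop/duplicate) edge before giving up
#: on the current step.
_STEP_ATTEMPTS = 100

ERG = "erg"
SW = "sw"
SF = "sf"
RP = "rp"

MODELS = (ERG, SW, SF, RP)


@dataclass(frozen=True)
class ModelParams:
    """Parameters of one baseline draw.

    Only the fields of the named model are meaningful: ``pe`` for the
    Gilbert model; ``k`` (even lattice degree) and ``beta`` (rewiring
    probability) for the small-world model; ``alpha``/``beta``/``gamma``
    (summing to 1) for the scale-free model.
    """

    model: str
    pe: float | None = None
    k: int | None = None
    beta: float | None = None
    alpha: float | None = None
    gamma: float | None = None

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        for name in ("pe", "beta", "alpha", "gamma"):
            value = getattr(self, name)
            if value is not None and not 0.0 <= value <= 1.0:
                raise ValueError(f"{name}={value} outside [0, 1]")
        if self.model == SF:
            total = (self.alpha or 0.0) + (self.beta or 0.0) + (self.gamma or 0.0)
            if abs(total - 1.0) > 1e-12:
                raise ValueError(f"alpha+beta+gamma must equal 1, got {total}")
        if self.model == SW and self.k is not None and self.k % 2 != 0:
            raise ValueError(f"lattice degree k must be even, got {self.k}")


def gilbert(n: int, pe: float, rng: np.random.Generator) -> SimpleDigraph:
    """Gilbert digraph: each of the ``N(N-1)`` ordered pairs included
    independently with probability ``pe``."""
    if n < 1:
        raise ValueError("need at least one vertex")
    if not 0.0 <= pe <= 1.0:
        raise ValueError(f"edge probability {pe} outside [0, 1]")
    mask = rng.random((n, n)) < pe
    np.fill_diagonal(mask, False)
    return SimpleDigraph.from_adjacency(mask)


def small_world(n: int, k: int, beta: float, rng: np.random.Generator) -> SimpleDigraph:
    """Directed Watts–Strogatz graph.

    Start from the reciprocal ring lattice in which each vertex is linked in
    both directions to its ``k`` nearest neighbours (``Nk`` directed edges),
    then visit every directed edge once and, independently with probability
    ``beta``, rewire its destination to a uniformly random vertex, redrawing
    on loops and duplicates.  With ``beta = 0`` every edge keeps its
    reciprocal twin, so the reciprocity is exactly one.
    """
    if k % 2 != 0 or not 2 <= k <= n - 1:
        raise ValueError(f"k must be even with 2 <= k <= N-1, got k={k}, N={n}")
    if not 0.0 <= beta <= 1.0:
        raise ValueError(f"rewiring probability {beta} outside [0, 1]")
    edges: set[tuple[int, int]] = set()
    for i in range(n):
        for off in range(1, k // 2 + 1):
            edges.add((i, (i + off) % n))
            edges.add((i, (i - off) % n))
    for u, v in sorted(edges):
        if rng.random() >= beta:
            continue
        for _ in range(_STEP_ATTEMPTS):
            w = int(rng.integers(0, n))
            if w != u and (u, w) not in edges:
                edges.remove((u, v))
                edges.add((u, w))
                break
    return SimpleDigraph(n, frozenset(edges))


def scale_free(
    n: int,
    alpha: float,
    beta: float,
    gamma: float,
    rng: np.random.Generator,
    delta_in: float = DELTA_IN,
    delta_out: float = DELTA_OUT,
) -> SimpleDigraph:
    """Directed scale-free growth graph, grown from a 3-cycle until ``n`` nodes.

    At each step, with probability ``alpha`` a new node is added with an
    out-edge to an existing node chosen proportionally to indegree +
    ``delta_in``; with probability ``beta`` an edge is added between two
    existing nodes (source by outdegree + ``delta_out``, destination by
    indegree + ``delta_in``); with probability ``gamma`` a new node is added
    with an in-edge from an existing node chosen by outdegree + ``delta_out``.
    Proposals that would create a loop or duplicate edge are redrawn in
    place (bounded attempts, then the step is skipped), so the output is
    simple.
    """
    if abs(alpha + beta + gamma - 1.0) > 1e-12:
        raise ValueError("alpha + beta + gamma must equal 1")
    if n < 3:
        raise ValueError("need at least 3 vertices (the seed cycle)")
    in_deg = np.zeros(n, dtype=np.float64)
    out_deg = np.zeros(n, dtype=np.float64)
    edges: set[tuple[int, int]] = {(0, 1), (1, 2), (2, 0)}
    in_deg[:3] = out_deg[:3] = 1.0
    num_nodes = 3

    def pick(weights: np.ndarray) -> int:
        cum = np.cumsum(weights)
        return int(min(np.searchsorted(cum, rng.random() * cum[-1], side="right"),
                       weights.size - 1))

    while num_nodes < n:
        r = rng.random()
        if r < alpha:
            w = pick(in_deg[:num_nodes] + delta_in)
            v = num_nodes
            edges.add((v, w))
            out_deg[v] += 1
            in_deg[w] += 1
            num_nodes += 1
        elif r < alpha + beta:
            for _ in range(_STEP_ATTEMPTS):
                u = pick(out_deg[:num_nodes] + delta_out)
                w = pick(in_deg[:num_nodes] + delta_in)
                if u != w and (u, w) not in edges:
                    edges.add((u, w))
                    out_deg[u] += 1
                    in_deg[w] += 1
                    break
        else:
            w = pick(out_deg[:num_nodes] + delta_out)
            v = num_nodes
            edges.add((w, v))
            out_deg[w] += 1
            in_deg[v] += 1
            num_nodes += 1
    return SimpleDigraph(n, frozenset(edges))


def sample_params(model: str, n: int, rng: np.random.Generator) -> ModelParams:
    """Draw one parameter set for a baseline model.

    Gilbert: ``pe ~ U(0,1)``.  Small-world: ``beta ~ U(0,1)`` and an even
    lattice degree ``k = 2 U{1, floor((N-1)/2)}``, so ensembles sweep the
    full density range.  Scale-free: ``alpha, beta, gamma`` as a normalized
    triple of independent ``U(0,1)`` draws.
    """
    if model == ERG:
        return ModelParams(ERG, pe=float(rng.uniform()))
    if model == SW:
        k = 2 * int(rng.integers(1, (n - 1) // 2 + 1))
        return ModelParams(SW, k=k, beta=float(rng.uniform()))
    if model == SF:
        raw = rng.uniform(size=3)
        a, b, g = (raw / raw.sum()).tolist()
        return ModelParams(SF, alpha=a, beta=b, gamma=g)
    raise ValueError(f"unknown model {model!r}")


def generate(params: ModelParams, n: int, rng: np.random.Generator) -> SimpleDigraph:
    """Dispatch a parameter set to its generator."""
    if params.model == ERG:
        return gilbert(n, params.pe, rng)
    if params.model == SW:
        return small_world(n, params.k, params.beta, rng)
    if params.model == SF:
        return scale_free(n, params.alpha, params.beta, params.gamma, rng)
    raise ValueError(f"no direct generator for model {params.model!r}")
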