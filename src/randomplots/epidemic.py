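"""Two-way rumor epidemic on a digraph, and the model-comparison experiment.

Unlike a one-way infection process, the rumor process lets every node act on
its out-neighbours in both directions of belief: a spoiled node tries to
pass the rumor to each not-yet-reached out-neighbour (per-edge probability
``p1``) and a healthy node tries to cure each spoiled out-neighbour with a
contradiction (per-edge probability ``p2``).  A node that has received the
contradiction is immune: it counts as healthy and can no longer be spoiled
(the classical spreader/stifler picture).  Updates are synchronous - states
freeze during an iteration and all changes apply together at its end.

Because curing is permanent the rumor always burns out in well-connected
graphs; what survives the iteration budget are structurally stranded
spoiled pockets - vertices no healthy node can ever reach along an edge.
After the budget the terminal state is classified as ``all_spoiled``,
``all_healthy`` (no spoiled node left) or ``mixed``; tallying these
outcomes over graph ensembles stratified by density reveals how much
dynamic diversity a graph generator supports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from randomplots.digraph import SimpleDigraph

logger = logging.getLogger(__name__)

ALL_SPOILED = "all_spoiled"
ALL_HEALTHY = "all_healthy"
MIXED = "mixed"

#: Initial-spoiled fractions and per-edge probabilities of the standard
#: 75-point experiment grid.
N0_GRID = (0.01, 0.05, 0.10)
P_GRID = (0.2, 0.4, 0.6, 0.8, 1.0)


@dataclass(frozen=True)
class EpidemicConfig:
    """One grid point of the rumor process.

    ``n0_fraction`` is the initially spoiled fraction of nodes, ``p1`` the
    per-edge infection probability, ``p2`` the per-edge cure probability,
    ``max_iters`` the synchronous-iteration budget.
    """

    n0_fraction: float
    p1: float
    p2: float
    max_iters: int = 100

    def __post_init__(self) -> None:
        for name in ("n0_fraction", "p1", "p2"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name}={value} outside [0, 1]")
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")


@dataclass(frozen=True)
class EpidemicOutcome:
    """Terminal classification of one run and the iterations it took."""

    terminal: str
    iterations_run: int


#: Node states: healthy and never spoiled / currently spreading the rumor /
#: healthy and immune (has received the contradiction).
SUSCEPTIBLE, SPOILED, CURED = np.int8(0), np.int8(1), np.int8(2)


def seed_infection(n: int, n0_fraction: float, rng: np.random.Generator) -> np.ndarray:
    """State vector with exactly ``round(n * n0_fraction)`` spoiled nodes,
    chosen uniformly without replacement; everyone else susceptible."""
    count = int(round(n * n0_fraction))
    state = np.full(n, SUSCEPTIBLE)
    if count > 0:
        state[rng.choice(n, size=count, replace=False)] = SPOILED
    return state


def _step_counts(
    at: sp.csr_matrix,
    state: np.ndarray,
    p1: float,
    p2: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One synchronous update given the transposed adjacency ``at``.

    Everything is evaluated in the frozen start-of-iteration state, and
    influence flows along edge direction (a node is acted on by its
    in-neighbours).  A susceptible node with ``k`` spoiled in-neighbours
    becomes spoiled with probability ``1 - (1-p1)^k`` (at least one of
    ``k`` independent per-edge attempts succeeds); a spoiled node with
    ``h`` healthy in-neighbours (susceptible or cured) becomes cured with
    probability ``1 - (1-p2)^h``.  The two target sets are disjoint, so no
    conflict resolution is needed.
    """
    spoiled = state == SPOILED
    spoiled_in = np.asarray(at @ spoiled.astype(np.float64))
    healthy_in = np.asarray(at @ (~spoiled).astype(np.float64))
    u = rng.random(state.size)
    new_state = state.copy()
    new_state[(state == SUSCEPTIBLE) & (u < 1.0 - (1.0 - p1) ** spoiled_in)] = SPOILED
    new_state[spoiled & (u < 1.0 - (1.0 - p2) ** healthy_in)] = CURED
    return new_state


def step(
    g: SimpleDigraph,
    state: np.ndarray,
    p1: float,
    p2: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One synchronous rumor iteration; influence flows along edge direction."""
    state = np.asarray(state, dtype=np.int8)
    if state.size != g.n:
        raise ValueError("state vector length must equal the vertex count")
    return _step_counts(sp.csr_matrix(g.to_sparse().T), state, p1, p2, rng)


def _classify(state: np.ndarray) -> str:
    spoiled = int((state == SPOILED).sum())
    if spoiled == 0:
        return ALL_HEALTHY
    if spoiled == state.size:
        return ALL_SPOILED
    return MIXED


def run(
    g: SimpleDigraph,
    config: EpidemicConfig,
    rng: np.random.Generator,
    _at: sp.csr_matrix | None = None,
) -> EpidemicOutcome:
    """Seed, iterate up to the budget, classify the terminal state.

    The uniform states are absorbing - with no spoiled node nothing can
    create a spreader, and with no healthy node nothing can cure - so the
    loop exits early once either is reached; the classification is
    identical to running out the full budget.
    """
    at = sp.csr_matrix(g.to_sparse().T) if _at is None else _at
    state = seed_infection(g.n, config.n0_fraction, rng)
    iterations = 0
    for iterations in range(1, config.max_iters + 1):
        spoiled = state == SPOILED
        if not spoiled.any() or spoiled.all():
            iterations -= 1
            break
        state = _step_counts(at, state, config.p1, config.p2, rng)
    return EpidemicOutcome(_classify(state), iterations)


def _run_batch(
    a_dense: np.ndarray,
    config: EpidemicConfig,
    reps: int,
    rng: np.random.Generator,
) -> dict[str, int]:
    """Terminal-state tally of ``reps`` independent runs on one graph.

    All repetitions share the parameters, so their state vectors are
    stacked into a matrix and stepped together: in-neighbour tallies for
    every run are one dense matrix product.  Distributionally identical to
    ``reps`` calls of :func:`run`; rows whose rumor has gone extinct (or
    saturated) drop out of the iteration early.
    """
    n = a_dense.shape[0]
    states = np.stack(
        [seed_infection(n, config.n0_fraction, rng) for _ in range(reps)]
    )
    active = np.ones(reps, dtype=bool)
    counts = {ALL_SPOILED: 0, ALL_HEALTHY: 0, MIXED: 0}
    for _ in range(config.max_iters):
        spoiled = states[active] == SPOILED
        done = ~spoiled.any(axis=1) | spoiled.all(axis=1)
        if done.any():
            for row in states[active][done]:
                counts[_classify(row)] += 1
            keep = np.flatnonzero(active)[~done]
            active = np.zeros(reps, dtype=bool)
            active[keep] = True
            if not active.any():
                return counts
            spoiled = states[active] == SPOILED
        spoiled_in = spoiled.astype(np.float64) @ a_dense
        healthy_in = (~spoiled).astype(np.float64) @ a_dense
        u = rng.random(spoiled.shape)
        sub = states[active]
        sub[(sub == SUSCEPTIBLE) & (u < 1.0 - (1.0 - config.p1) ** spoiled_in)] = SPOILED
        sub[(sub == SPOILED) & (u < 1.0 - (1.0 - config.p2) ** healthy_in)] = CURED
        states[active] = sub
    for row in states[active]:
        counts[_classify(row)] += 1
    return counts


def run_grid(
    graphs: Sequence[SimpleDigraph],
    reps: int,
    rng: np.random.Generator,
    n0_grid: Sequence[float] = N0_GRID,
    p_grid: Sequence[float] = P_GRID,
    max_iters: int = 100,
) -> pd.DataFrame:
    """Run the full (N0, p1, p2) grid over an ensemble of graphs.

    For every grid combination, every graph is run ``reps`` times.  Returns
    one row per grid point with terminal-state counts.
    """
    dense = [g.to_adjacency().astype(np.float64) for g in graphs]
    rows = []
    for n0 in n0_grid:
        for p1 in p_grid:
            for p2 in p_grid:
                config = EpidemicConfig(n0, p1, p2, max_iters=max_iters)
                counts = {ALL_SPOILED: 0, ALL_HEALTHY: 0, MIXED: 0}
                for a in dense:
                    batch = _run_batch(a, config, reps, rng)
                    for key, value in batch.items():
                        counts[key] += value
                rows.append(
                    {
                        "n0": n0,
                        "p1": p1,
                        "p2": p2,
                        "n_runs": len(graphs) * reps,
                        "n_mixed": counts[MIXED],
                        "n_all_healthy": counts[ALL_HEALTHY],
                        "n_all_spoiled": counts[ALL_SPOILED],
                    }
                )
    return pd.DataFrame(rows)


def binned_mixed_state_experiment(
    models: Sequence[str],
    density_bins: Sequence[tuple[float, float]],
    n_graphs: int,
    reps: int,
    rng: np.random.Generator,
    n: int = 300,
    n0_grid: Sequence[float] = N0_GRID,
    p_grid: Sequence[float] = P_GRID,
    max_attempts: int = 10_000,
) -> pd.DataFrame:
    """Mixed-terminal-state tally per model x density bin, over the full grid.

    For each model and bin, ``n_graphs`` graphs are rejection-sampled into
    the bin, every grid combination is run ``reps`` times per graph, and the
    per-grid-point terminal-state counts are recorded.  A bin a model cannot
    reach (the attempt cap is hit on a graph) is recorded as unavailable:
    a single row with ``n_runs = 0``.

    The headline one-number-per-cell summary - the percentage of *all* runs
    in the cell that end mixed - is obtained with :func:`summarize_mixed`.
    """
    from randomplots.ensembles import BinUnreachableError, EnsembleSpec, generate_ensemble

    frames = []
    for model in models:
        for bin_lo, bin_hi in density_bins:
            spec = EnsembleSpec(
                model=model,
                n_graphs=n_graphs,
                n=n,
                density_bin=(bin_lo, bin_hi),
                max_attempts=max_attempts,
            )
            try:
                pairs = generate_ensemble(spec, rng)
            except BinUnreachableError:
                logger.info("bin [%s, %s) unreachable for model %s", bin_lo, bin_hi, model)
                frames.append(
                    pd.DataFrame(
                        [{"model": model, "bin_lo": bin_lo, "bin_hi": bin_hi,
                          "n0": np.nan, "p1": np.nan, "p2": np.nan, "n_runs": 0,
                          "n_mixed": 0, "n_all_healthy": 0, "n_all_spoiled": 0}]
                    )
                )
                continue
            graphs = [g for _, g in pairs]
            grid = run_grid(graphs, reps, rng, n0_grid=n0_grid, p_grid=p_grid)
            grid.insert(0, "model", model)
            grid.insert(1, "bin_lo", bin_lo)
            grid.insert(2, "bin_hi", bin_hi)
            frames.append(grid)
            logger.info(
                "model %s bin [%s, %s): %d graphs, %.2f%% mixed",
                model, bin_lo, bin_hi, len(graphs),
                100.0 * grid["n_mixed"].sum() / grid["n_runs"].sum(),
            )
    return pd.concat(frames, ignore_index=True)


def summarize_mixed(table: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a grid table to one mixed percentage per model x bin cell.

    Cells recorded as unavailable get ``NaN``.
    """
    def pct(group: pd.DataFrame) -> float:
        runs = group["n_runs"].sum()
        return 100.0 * group["n_mixed"].sum() / runs if runs else float("nan")

    out = (
        table.groupby(["model", "bin_lo", "bin_hi"])
        .apply(pct, include_groups=False)
        .rename("pct_mixed")
        .reset_index()
    )
    return out
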