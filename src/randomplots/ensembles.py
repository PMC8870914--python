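"""Ensemble generation, density binning, metric clouds and accuracy sweeps.

An ensemble is a list of independently parameterized graphs from one model:
the degree-plot-targeted generator ("rp") or one of the baselines.  Each
graph gets freshly sampled parameters, so the ensemble sweeps the model's
reachable region of parameter space.  Ensembles can be restricted to one of
the five standard density bins by rejection sampling on the realized
density; for the plot-targeted model the density is known from the
reference pair before the (expensive) graph synthesis, so rejection happens
upfront.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from randomplots import baselines, builder, metrics, rvdp
from randomplots.digraph import SimpleDigraph

logger = logging.getLogger(__name__)

#: The standard density partition; all bins half-open except the last.
DENSITY_BINS: tuple[tuple[float, float], ...] = (
    (0.0, 0.2),
    (0.2, 0.4),
    (0.4, 0.6),
    (0.6, 0.8),
    (0.8, 1.0),
)


class BinUnreachableError(RuntimeError):
    """A model exhausted its attempt budget without hitting the density bin."""


@dataclass(frozen=True)
class EnsembleSpec:
    """What to generate: model, ensemble size, graph size, optional density bin."""

    model: str
    n_graphs: int
    n: int
    seed: int | None = None
    density_bin: tuple[float, float] | None = None
    max_attempts: int = 10_000

    def __post_init__(self) -> None:
        if self.model not in baselines.MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        if self.n_graphs < 1:
            raise ValueError("n_graphs must be >= 1")


def _in_bin(d: float, bin_: tuple[float, float]) -> bool:
    lo, hi = bin_
    if math.isclose(hi, 1.0):
        return lo <= d <= hi
    return lo <= d < hi


def rp_graph(
    n: int, rng: np.random.Generator, density_bin: tuple[float, float] | None = None,
    max_attempts: int = 10_000,
) -> builder.BuildResult:
    """One graph from the plot-targeted model, optionally density-binned.

    The synthesized graph has exactly ``D`` edges (the reference degree
    sum), so its density is known before synthesis and rejection into a bin
    only repeats the cheap reference sampling.
    """
    for _ in range(max_attempts):
        reference = rvdp.generate_rvdp(n, rng)
        if density_bin is None or _in_bin(reference.density, density_bin):
            return builder.build(reference, rng)
    raise BinUnreachableError(
        f"no reference pair landed in bin {density_bin} after {max_attempts} attempts"
    )


def generate_ensemble(
    spec: EnsembleSpec, rng: np.random.Generator | None = None
) -> list[tuple[object, SimpleDigraph]]:
    """Generate ``spec.n_graphs`` graphs, each from fresh parameters.

    Returns ``(params, graph)`` pairs; for the plot-targeted model
    ``params`` is the :class:`~randomplots.builder.BuildResult` (which
    carries the reference pair, the shuffle and the L1 errors).  Raises
    :class:`BinUnreachableError` if a graph exhausts the attempt budget
    without landing in the requested density bin.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    out: list[tuple[object, SimpleDigraph]] = []
    rejected = 0
    for _ in range(spec.n_graphs):
        if spec.model == baselines.RP:
            result = rp_graph(spec.n, rng, spec.density_bin, spec.max_attempts)
            out.append((result, result.graph))
            continue
        for attempt in range(spec.max_attempts):
            params = baselines.sample_params(spec.model, spec.n, rng)
            graph = baselines.generate(params, spec.n, rng)
            d = graph.num_edges / (spec.n * (spec.n - 1))
            if spec.density_bin is None or _in_bin(d, spec.density_bin):
                out.append((params, graph))
                break
            rejected += 1
        else:
            raise BinUnreachableError(
                f"model {spec.model!r} exhausted {spec.max_attempts} attempts "
                f"for bin {spec.density_bin}"
            )
    logger.info(
        "ensemble: model=%s n=%d graphs=%d bin=%s rejected=%d",
        spec.model, spec.n, len(out), spec.density_bin, rejected,
    )
    return out


def cloud(
    spec: EnsembleSpec,
    metric_name: str,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """(density, metric) points of a fresh ensemble, for coverage plots.

    One row per graph on which the metric is defined; the number of graphs
    with an undefined value is attached as ``frame.attrs['n_undefined']``.
    """
    if metric_name not in metrics.METRIC_NAMES:
        raise ValueError(f"unknown metric {metric_name!r}")
    pairs = generate_ensemble(spec, rng)
    rows = []
    undefined = 0
    for i, (_, graph) in enumerate(pairs):
        value = metrics.compute(graph, metric_name)
        if value is None:
            undefined += 1
            continue
        rows.append({"graph_id": i, "density": metrics.density(graph), metric_name: value})
    frame = pd.DataFrame(rows, columns=["graph_id", "density", metric_name])
    frame.attrs["n_undefined"] = undefined
    return frame


def run_accuracy_experiment(
    n_graphs: int, n: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Synthesis accuracy against construction parameters.

    For each of ``n_graphs`` independent draws: sample the reference line
    pair, record its parameters, synthesize the graph and report the graph
    density together with the averaged L1 error ``(L- + L+) / 2``.
    """
    if n < 2:
        raise ValueError("need at least 2 vertices")
    rows = []
    for _ in range(n_graphs):
        line1, line2 = rvdp.sample_line_pair(n, rng)
        plot1, plot2 = rvdp.discretize(line1), rvdp.discretize(line2)
        if rng.integers(0, 2) == 0:
            reference = rvdp.balance(plot1, plot2, rng)
        else:
            reference = rvdp.balance(plot2, plot1, rng)
        result = builder.build(reference, rng)
        rows.append(
            {
                "density": reference.density,
                "avg_error": 0.5 * (result.l_minus + result.l_plus),
                "alpha1": line1.alpha,
                "alpha2": line2.alpha,
                "beta1": line1.beta,
            }
        )
    return pd.DataFrame(rows)
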