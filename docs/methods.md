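# Methods

## The problem

When a complex system must be modeled as a network but nothing reliable is
known about its connection structure — protein interaction maps, signal
flows, social contact networks too costly to measure — any single random
graph null model imports a strong, unverifiable assumption about the degree
distribution.  This package takes the opposite approach: generate an
*ensemble* of simple digraphs whose degree distributions deliberately span a
wide range of shapes, so that conclusions drawn "over the ensemble" do not
hinge on one guessed structure.

## Reference degree plots

A *vertex degree plot* (VDP) is the array of a graph's vertex degrees sorted
ascending; a digraph has an in-plot and an out-plot.  The generator first
samples a *reference* pair `(D-, D+)` of nondecreasing integer arrays of
length `N` with entries in `[1, N-1]` and equal sums `D`:

1. Draw an angle `α₁ ~ U(0, π/2)` and a shift `δ ~ U(0, N)` along one of the
   two sides of the `N × N` square adjacent to the origin (direction by fair
   coin), giving a line `y₁(x) = x·tan α₁ + β₁` with `β₁ = δ` (shift up) or
   `β₁ = -δ·tan α₁` (shift right).
2. Draw `α₂ ~ U(0, π/2)` independently and solve for `β₂` so the areas under
   the two lines, clamped into the square, agree (the clamped area is a
   piecewise-linear, nondecreasing function of the intercept, computed
   analytically; `β₂` is found by bisection over `[-N·tan α₂, N]` to half a
   unit cell, `tol = 0.5`, at most 200 iterations).
3. Round each line to integers at abscissae `i = 1..N`:
   `floor(max(min(y(i) + 0.5, N-1), 1))` — round half up, clamped into
   `[1, N-1]`.  The lower clamp at 1 means every vertex targets at least one
   in- and one out-edge.
4. Assign the two integer plots to the in/out sides by a fair coin.
5. Rounding misaligns the two sums by at most `3N`; the gap is repaired by
   repeatedly drawing an index `k ~ U{1..N}` and one of two unit moves
   (increment the deficit side if it stays `≤ N-1`, decrement the surplus
   side if it stays `≥ 1`), discarding draws whose move would violate its
   bound.  Each applied move shrinks the gap by one and an applicable move
   always exists, so this terminates; the whole sampler is `O(N)` time and
   space.

Angles are sampled in `(ε, π/2 - ε)` with `ε = 1e-9` to keep `tan` finite.
Unit moves at interior indices can break sortedness, so both arrays are
re-sorted at the end — reference plots are *defined* as sorted arrays, and
downstream code relies on it.  The shift range toward either side of the
square is taken symmetric (`δ ~ U(0, N)` both ways).

The family of shapes reachable this way — one clamped line segment — covers
convex staircases, near-uniform plots and steep "few hubs, many leaves"
profiles, and the induced edge count `D` spans essentially the whole density
interval `(0, 1]`.  It cannot represent plots with an interior hinge at
intermediate height (piecewise-linear references with breakpoints would be
the natural extension).

## Graph synthesis

Given a reference pair, a simple digraph with *exactly* `D` edges is grown
edge by edge.  A permutation `σ` (uniform by default) decouples each
vertex's outdegree target `D+(σ(i))` from its indegree target `D-(i)` —
both arrays are sorted, so without shuffling the two targets would be
strongly positively correlated.  Each step:

1. A fair coin picks which side is drawn first (indegree or outdegree).
2. The first endpoint is drawn among vertices that can still accept a new
   edge on that side without creating a loop or duplicate, with probability
   proportional to its **remaining target capacity** (target minus current
   degree); the partner is then drawn the same way among the vertices not
   already linked to it.
3. If every admissible vertex has exhausted its capacity the draw falls back
   to uniform over the admissible set.  The fallback is what lets the loop
   always complete to `D` edges: not every equal-sum target pair is
   realizable by a simple digraph — `(1,1,1,4,4)` against itself is a
   5-vertex counterexample, confirmed by the package's exhaustive
   `is_realizable` oracle — and near-ceiling targets (`≈ N-1`) routinely
   exceed what simplicity allows.

Remaining-capacity weighting is the sequential configuration-model scheme:
vertices stop attracting edges once their target is met, so feasible
targets are realized essentially exactly, and in particular every vertex
reaches its minimum of one in- and one out-edge whenever the targets permit.
Misses concentrate where the reference hugs the ceiling — the steep top
segment — while the fallback spreads the surplus thinly over low-target
vertices.  This "smoothing" of the actual plot relative to a steep reference
is quantified by the L1 errors

    L± = Σᵢ |deg±(vᵢ) − target±(i)| / (N(N−1)),

compared per assigned vertex target (a sorted-plot variant is provided for
overlay-style comparisons).  Accuracy is best for shallow references at low
density, degrades with steepness, and peaks at intermediate densities where
structural variety is largest; `run_accuracy_experiment` reproduces this
sweep at any scale.

Synthesis is `O(D·N)` with dense boolean adjacency bookkeeping — worst case
`O(N³)` — which is fine for the small-to-medium graphs (`N` up to a few
thousand) the package targets.

## Baseline generators

Three classical directed null models serve as comparison points, each with
a per-graph parameter-sampling scheme so an ensemble sweeps its reachable
density range:

- **Erdős–Rényi–Gilbert**: every ordered pair an edge independently with
  `pe ~ U(0,1)`.
- **Directed small-world**: reciprocal ring lattice (`k` nearest neighbours,
  both directions, `Nk` edges), then each directed edge independently with
  probability `β ~ U(0,1)` has its destination rewired to a uniform vertex,
  redrawing on loops/duplicates.  The lattice degree is drawn as
  `k = 2·U{1, ⌊(N-1)/2⌋}`, so densities cover `(0, 1)`.  Which endpoint the
  rewiring moves is a free choice; moving the destination is the variant
  used here.
- **Directed scale-free growth** from a 3-cycle seed: with probability `α`
  add a node with an out-edge to a target chosen ∝ indegree + δ_in; with
  `β` add an edge between existing nodes (source ∝ outdegree + δ_out,
  destination ∝ indegree + δ_in); with `γ` add a node with an in-edge.
  `(α, β, γ)` is a normalized triple of `U(0,1)` draws; the smoothing
  constants are the conventional `δ_in = 0.2`, `δ_out = 0`.  Loop/duplicate
  proposals are redrawn in place (100 attempts, then the step is skipped) so
  the output is simple.  Growth adds at most one edge per step, so dense
  graphs are unreachable for this model — a fact the ensemble harness
  surfaces as an explicit bin-exhaustion error rather than a silent skip.

## Diversity metrics

Eight scalar properties per graph, chosen to be meaningful for directed
graphs and defined for (almost) arbitrary ones: density, average
reachability (mean fraction of *other* vertices reachable by a directed
path), largest strongly connected component, spectral bipartivity
(`tr cosh A / tr exp A` on the asymmetric adjacency, exact via dense matrix
exponentials, `O(N³)`), reciprocity, transitivity over ordered vertex
triples (open wedges `u→v→w` closed by `u→w`, counted via `A²`), the
directed (Fagiolo) clustering coefficient averaged over vertices, and mean
eigenvector centrality accumulated along in-edges.  Standard algorithms are
delegated to networkx; the matrix-function bipartivity and the triple-based
transitivity are computed directly and cross-checked against independent
oracles in the tests.  Undefined values (reciprocity of an edgeless graph,
transitivity without wedges, non-convergent centrality) are recorded as
missing, never as zero, so ensemble clouds are not distorted.  Eigenvector
centrality uses networkx's shifted power iteration, which converges even on
nilpotent (DAG) adjacencies by accumulating mass at sink hubs; graphs where
it genuinely fails to converge are recorded as missing.

## The rumor epidemic

The dynamic-diversity assay runs a two-way rumor process: nodes are
*susceptible* (healthy, never reached), *spoiled* (spreading the rumor) or
*cured* (healthy and immune, having received the contradiction).  Per
synchronous iteration, evaluated in the frozen state, influence flowing
along edge direction:

- a susceptible node with `k` spoiled in-neighbours becomes spoiled with
  probability `1 - (1-p1)^k` (independent per-edge attempts);
- a spoiled node with `h` healthy in-neighbours becomes cured with
  probability `1 - (1-p2)^h`.

Treating the contradiction as immunizing is the package's resolution of the
underdetermined two-state wording of rumor models: with re-infectable
cured nodes the process turns endemic and essentially every run on a
connected graph ends mixed, which contradicts the benchmark behaviour this
assay is meant to reproduce (rumor extinction in well-connected graphs,
mixed states only where spoiled vertices sit out of reach of any healthy
influencer, and no saturation to all-spoiled).  With immunity the process
is SIR-like: it always burns out, and what survives a 100-iteration budget
is structural — chiefly vertices with no in-edges (common in scale-free
growth graphs, where they make the overwhelming majority of runs end
mixed; rare elsewhere) and spoiled pockets that no healthy vertex can
reach.

The standard experiment seeds `round(N·N0)` spoiled nodes for
`N0 ∈ {1, 5, 10}%`, sweeps `p1, p2 ∈ {0.2, 0.4, 0.6, 0.8, 1}` (75 grid
combinations), and tallies terminal states (all-spoiled / all-healthy /
mixed) over graph ensembles stratified into the five density bins
`[0, .2), [.2, .4), [.4, .6), [.6, .8), [.8, 1]`.  Ensembles are
rejection-sampled into bins on realized density (for the plot-targeted
model the density is known from the reference pair before synthesis, so
rejection is cheap); a model that cannot reach a bin raises an explicit
exhaustion error and the cell is reported unavailable.

## Problem sizes

The reference experiments use 100 graphs per model-bin cell and 10
repetitions per graph per grid point (1000 runs per combination).
`scripts/acceptance.py` runs that full scale for the six headline cells
(about ten minutes on one CPU thanks to the vectorized synchronous update).
The test suite uses 30 graphs × 5 repetitions for the percentage checks, 20
× 3 for the qualitative zero cells, and 25 graphs × 40 repetitions (the
same 1000 runs per combination as the reference) for the both-states count,
whose expected value scales with runs per combination rather than with the
percentage.

## Known limitations

- Single-segment reference lines cannot express hinged degree plots
  (e.g. leaf-mass + bulk + hub profiles); piecewise references are future
  work.
- Dense synthesis is cubic; ensembles of graphs beyond a few thousand
  vertices need a faster (e.g. multigraph-based) builder.
- The small-world mixed-state percentage is sensitive to the unknown
  lattice-degree distribution of the reference experiments; under the
  uniform even-`k` scheme used here most sparse-bin lattices are too well
  connected to strand the rumor, and the package reproduces a lower
  percentage than the reference table.
- Metrics with dense `O(N³)` kernels (spectral bipartivity) are impractical
  beyond `N ≈ 3000`.
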