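# randomplots

Diverse random-digraph ensembles for modeling systems whose connection
structure is unknown.

When a complex system — a signaling network, an interaction map, a contact
network — must be modeled as a graph but its wiring cannot be measured,
picking any single random-graph null model (Erdős–Rényi–Gilbert,
small-world, scale-free) silently fixes the degree distribution.  This
package instead generates an *ensemble* of simple digraphs whose sorted
degree arrays ("vertex degree plots") track randomly drawn piecewise-linear
reference shapes, so the ensemble spans sparse and dense, flat and
hub-dominated structures alike.  Conclusions that hold across such an
ensemble do not hinge on a guessed distribution.

The generator works in two stages:

1. **Reference plots.** Sample a pair of nondecreasing integer arrays
   `D⁻, D⁺ : {1..N} → {1..N−1}` with equal sums `D`, by drawing two random
   clamped lines of equal area over the `N × N` square, rounding them to
   integers, and repairing the rounding mismatch with random unit moves.
2. **Synthesis.** Grow a simple digraph edge by edge until `|E| = D`,
   drawing endpoints with probability proportional to their remaining
   target capacity (a sequential configuration-model scheme), so the
   realized in/out degree plots approximate `D⁻` and `D⁺ ∘ σ` for a random
   decorrelating permutation `σ`.  Accuracy is scored by
   `L± = Σᵢ |deg±(vᵢ) − target±(i)| / (N(N−1))`.

Alongside the generator: the three classical baselines in directed form
with parameter-sampling schemes, seven scalar diversity metrics (average
reachability, largest strongly connected component, spectral bipartivity,
reciprocity, transitivity, directed clustering, eigenvector centrality),
and a two-way rumor-epidemic assay that probes how diverse the *dynamics*
on an ensemble can be.  See `docs/methods.md` for the model details and
design choices.

## Worked example

```python
import numpy as np
from randomplots import generate_rvdp, build, compute_all

rng = np.random.default_rng(42)
ref = generate_rvdp(100, rng)          # reference degree-plot pair
result = build(ref, rng)               # simple digraph with |E| = D
record = compute_all(result.graph)

print(f"edges      : {result.graph.num_edges} (density {record.density:.3f})")
print(f"L- / L+    : {result.l_minus:.4f} / {result.l_plus:.4f}")
print(f"largest SCC: {record.largest_scc}")
print(f"reciprocity: {record.reciprocity:.3f}")
```

Output:

```
edges      : 9364 (density 0.946)
L- / L+    : 0.0303 / 0.0378
largest SCC: 100
reciprocity: 0.947
```

This seed happened to draw a very dense reference: 9364 of the 9900
possible edges.  The built graph has exactly that many edges, and its
degree plots deviate from the targets by 3–4% of the maximum possible L1
error per side — near-ceiling targets cannot all be met simultaneously, so
the misses sit at the steep top of the reference plot.  A density-0.95
graph is strongly connected (one 100-vertex component) and its reciprocity
is close to the density, as for an unstructured random digraph; other
seeds land anywhere in the density interval, which is the point of the
model.

Not every target pair is realizable — in/out sequences `(1,1,1,4,4)` admit
no simple digraph under any pairing, which `is_realizable` confirms by
exhaustive search, and `build` then completes to 11 edges with a forced
positive error.

A command-line interface mirrors the library:

```sh
rp generate --n 100 --seed 1 --count 5 --out plots.csv
rp build --n 100 --seed 1 --count 10 --out-dir graphs/
rp baseline --model sw --n 100 --seed 2 --count 10 --out-dir graphs/
rp metrics --in-dir graphs/ --out metrics.csv
rp epidemic --n 300 --graphs 20 --reps 3 --seed 3 --out table.csv
rp clouds --model rp --metric transitivity --n 100 --graphs 200 --seed 4 --out cloud.csv
rp accuracy --n 200 --graphs 500 --seed 5 --out accuracy.csv
```

Graphs are written as plain 1-based edge lists with a `# n=<N>` header and
a JSON sidecar (parameters, targets, permutation, errors); tables as CSV.

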