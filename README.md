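# lrfdist — Labeled Robinson–Foulds distance for event-labeled gene trees

Gene trees carry more than topology: reconciliation with a species tree
labels each internal node with the evolutionary event behind it —
speciation, duplication, horizontal transfer — and these labels determine
orthology and paralogy calls. Comparing two such trees with the plain
Robinson–Foulds (RF) distance throws the labels away; comparing labelings
alone ignores topology. `lrfdist` implements the **Labeled Robinson–Foulds
(LRF) distance**, a true metric on event-labeled trees computed exactly in
linear time, for anyone benchmarking gene tree inference or reconciliation
pipelines (e.g. against Ensembl Compara–style trees with NHX duplication
tags).

## The distance

For trees `T`, `T'` on the same leaf set `L`, with internal-node labels from
a finite alphabet `Λ`, three edit operations are allowed:

- **node deletion** `Del(x, y)` — contract the internal edge `{x, y}`;
- **node insertion** `Ins(x, y, Z, λ)` — split a node `y` of degree ≥ 4,
  moving a neighbor subset `Z` (`2 ≤ |Z| ≤ deg(y) − 2`) to a new node `x`
  labeled `λ`;
- **label substitution** `Sub(x, λ)`.

`LRF(T, T')` is the length of a shortest sequence of these operations
transforming `T` into `T'`. Leaves are never touched; with a single label
LRF reduces exactly to RF.

The algorithm rests on a decomposition into **islands**: maximal subtrees
whose internal edges are all *bad* (bipartition not shared with the partner
tree) and whose terminal edges are all good. Islands of `T` and `T'`
correspond one-to-one, and a pair `(I, I')` with `ε` and `ε'` internal bad
edges costs `ε + ε'` edits, plus one substitution iff the two islands share
no label. Summing over the `n` island pairs:

```
LRF(T, T') = Σᵢ (ε(Iᵢ) + ε(Iᵢ')) + δ  =  RF(T, T') + δ
```

where `δ` counts label-disjoint island pairs. Shared clades are found in
O(1) each via Day's postorder interval table, so the whole computation is
O(n). The package also *constructs* an explicit minimum edit path and can
replay it, and ships independent brute-force oracles (bipartition
enumeration; exhaustive edit-space search) that the test suite checks the
fast algorithm against.

## Worked example

```python
from lrfdist import compare_trees, worked_example_pair

t1, t2 = worked_example_pair()   # 8 leaves, speciation/duplication labels
report = compare_trees(t1, t2)
print(report.lrf, report.rf, report.delta)
```

Running `python examples/compare_trees.py` prints:

```
LRF = 7   (RF = 5 topological edits + delta = 2 label substitutions)

island pair breakdown:
  pair 1 (around leaves A,B): eps=0 eps'=0 shared label -> 0 edits
  pair 2 (around leaves C): eps=0 eps'=0 label-disjoint -> 1 edits
  pair 3 (around leaves E,F): eps=0 eps'=0 shared label -> 0 edits
  pair 4 (around leaves D,I,J): eps=3 eps'=2 label-disjoint -> 6 edits
```

The two trees differ in 5 bipartitions (all inside the island around
D, I, J) and in the labels of two island pairs, so 7 edit operations are
needed — and `edit_path` returns exactly such a sequence (3 deletions,
2 substitutions, 2 insertions; see `examples/edit_path_replay.py`, which
replays it and verifies the result equals the target).

Other example scripts: `examples/perturbation_experiment.py` (how RF and
LRF track a known number of random edits) and
`examples/scaling_benchmark.py` (linear growth of the elementary work, R²
= 1.000 on n = 100 … 10,000).

## Command line

```
lrfdist compare T1.nhx T2.nhx --label-policy nhx --format json --edit-path
lrfdist perturb T.nwk -k 10 --seed 42 --p-sub 0.3
lrfdist random-tree -n 100 --labels speciation,duplication --seed 1
lrfdist benchmark --sizes 100,1000,10000
```

Label policies: `name` (internal node names are labels), `nhx`
(`[&&NHX:D=Y]` → duplication, `D=N` → speciation, `H=Y`/`T=Y` → transfer),
`none` (unlabeled; LRF = RF). Exit codes distinguish parse errors (2) from
leaf-set mismatches (3).

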