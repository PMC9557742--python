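# Methods

## Model

`lrfdist` compares unordered trees on a common leaf set `L` whose internal
nodes carry *event labels* from a finite alphabet `Λ` (any number of label
types; nothing is hard-coded to the speciation/duplication case). The
Labeled Robinson–Foulds distance is defined as the minimum number of labeled
node edit operations — deletion, insertion-with-label, label substitution —
transforming one tree into the other, with leaves untouched. The
implementation computes it through the island decomposition:

1. **Normal form.** Both trees are brought to a shared *leaf-rooted* form.
   Rooted inputs get a reserved dummy leaf (`__lrf_root__`) grafted at the
   root and are re-rooted at it; unrooted inputs are rooted at the
   lexicographically smallest leaf (deterministic where any leaf would do).
   Clades of the normal form are in bijection with bipartitions of the
   input, so rooted and unrooted pairs are handled by one code path. A
   rooted/unrooted mixture is an error unless the caller opts into
   comparing both as unrooted. A collision with the reserved dummy name is
   an error, never a silent rename.
2. **Shared clades in O(n)** (Day's structure). Leaves of the first tree
   are renumbered 1..n in postorder, making every clade a contiguous
   interval `[l, r]` stored in an n-row table — at row `l` when the node is
   the last child of its parent, else at row `r`, which always finds a free
   row. One bottom-up pass over the second tree computes (min, max, size)
   triples; a clade is shared ("good") iff it is contiguous
   (`max − min + 1 = size`) and present in the table.
3. **Islands.** Internal nodes joined by bad edges form island cores (a
   union of one pass over each tree); `ε` = core size − 1 bad edges. Each
   island is matched to its partner through its unique *parent* boundary
   edge — the good clade interval above its topmost node, or a ROOT
   sentinel for the island adjacent to the root leaf — which realizes the
   island bijection in O(n) without materializing terminal-edge sets.
4. **Distance.** `LRF = Σ(εᵢ + εᵢ′) + δ`, with `δ` the number of island
   pairs whose label *sets* are disjoint (sets, not multisets: one shared
   label suffices to avoid the substitution). `RF = Σ(εᵢ + εᵢ′)` falls out
   of the same table, so `LRF = RF + δ` holds by construction and is
   cross-checked in tests against an independent bipartition enumeration.

## Edit paths

`edit_path` emits a concrete operation sequence of length exactly LRF: per
island pair, `ε` deletions collapse the source island to a star around a
survivor — the first node in postorder carrying a label shared with the
partner island when one exists (a deterministic tie-break that never
changes the length) — then one substitution exactly for label-disjoint
pairs, then `ε′` insertions obtained by collapsing the *target* island in a
simulation and inverting the recorded deletions. Replay is validated by a
canonical-form isomorphism test. Inserted nodes get fresh, deterministic
ids carried inside the operations so paths replay bit-identically.

## Edit semantics on rooted trees

The theory lives on unrooted trees; a rooted tree is read as its unrooted
version with a dummy leaf at the root. Applying operations directly to a
rooted tree therefore treats the root as one degree higher than its actual
degree (the virtual dummy), and insertions never displace the root. This
keeps the simulator's edits on rooted inputs consistent with the distance.

## Oracles

Two independent references exist solely for testing: RF by explicit
bipartition-set symmetric difference (O(n²), any size), and LRF by
breadth-first (uniform-cost, unit weights) search over edit space with
states deduplicated by canonical form. Insertion and substitution labels
are drawn from the union of the two trees' alphabets; an optimal path never
needs others, since the island-wise construction uses only labels present
in the target (and one shared label at most). Exceeding the search budget
raises a distinct error rather than returning a value. The search is
feasible to ~6 leaves; the test suite sweeps *all* 162 unrooted 5-leaf
2-label trees and compares every pair against the fast algorithm.

## Random trees and the perturbation protocol

`random_labeled_tree` grows a rooted topology by sequential random leaf
attachment (every current edge equally likely), optionally contracts each
internal edge with probability 0.25 for multifurcating shapes, and assigns
i.i.d. uniform labels; everything is driven by one integer seed and is
iterative, so 10,000-leaf trees generate without recursion issues.

`perturb` applies k sequential random edits: with probability `p_sub = 0.3`
a label substitution on a uniform internal node (new label uniform over
`Λ` minus the current one); the remaining 0.7 spread evenly over all
candidate moves — every internal edge (deletion; the surviving endpoint is
chosen uniformly, the two orientations being equivalent) and every node of
degree > 3 (insertion; the moved subset is uniform over all legal subsets,
the inserted label uniform over `Λ`). When one move class has no candidates
(a strictly binary tree admits no insertion; a star no deletion) its mass
goes to the other class rather than resampling. These defaults are the
simulation conditions used throughout the tests; the experiment runner
reports (replicate, k, rf, lrf, delta) rows.

What the simulator emulates — and does not: it produces uniform-attachment
topologies and i.i.d. labels, not birth–death shapes, and its edits are
uniform over candidates rather than biologically weighted, so passing tests
demonstrate correctness of the distance and the protocol's documented
distribution, not realism of any particular gene family.

## Numerical and design choices

- **Sizes.** The linear-scaling check uses n ∈ {100; 1,000; 10,000} with
  3 replicates and asserts R² > 0.99 of a linear fit to elementary
  operation counts (node visits + table writes); wall-clock is printed but
  never asserted. The exhaustive oracle sweep covers all 13,203 unordered
  pairs of 5-leaf 2-label trees; randomized suites use 200–500 seeded
  pairs/triples with n up to 40.
- **Labels** are normalized to lower case on parse (NHX dialects vary);
  the alphabet is open-ended.
- **Multifurcations** are first-class everywhere (the theory requires
  degree ≥ 3, not binarity); degree-2 non-root nodes are suppressed on
  parse.
- **Rootedness inference**: explicit argument > `[&R]`/`[&U]` hint > basal
  bifurcation ⇒ rooted. Real datasets are inconsistent here, so the
  decision is overridable everywhere.
- **Unlabeled and partially annotated inputs** are a policy, not a guess:
  `none` assigns a sentinel label to every internal node (LRF then equals
  RF exactly); under `name`/`nhx` a missing annotation is an error.
- **Degenerate inputs**: trees need ≥ 2 leaves; a 2-leaf rooted tree has a
  single internal node and compares by label only; identical trees give
  one star island per internal node and distance 0.

## Limitations

- Weighted edit operations are out of scope: island-wise optimality breaks
  when substitutions and indels have different costs.
- Substitutions that are biologically impossible under a given species
  tree are not banned; labels are compared purely symbolically.
- The edge-based labeled variant of the distance (contract/extend/flip,
  which upper-bounds this one) is documented history, not implemented.
- The search oracle is exponential and intentionally capped; it exists to
  certify the fast algorithm on small instances, not for production use.
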