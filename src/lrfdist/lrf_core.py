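"""Labeled Robinson-Foulds distance: islands, pairing, distance, edit paths.

The labeled Robinson-Foulds distance LRF(T, T') between two event-labeled
trees on the same leaf set is the length of a shortest sequence of labeled
node edit operations (node deletion, node insertion with a label, label
substitution) transforming T into T'.  It decomposes over *islands* —
maximal subtrees whose internal edges are all "bad" (bipartition not shared
with the partner tree) and whose terminal edges are all good.  Islands of
the two trees correspond one-to-one; a pair (I, I') with eps and eps'
internal bad edges costs eps + eps' edits if the two islands share an
internal-node label, one more otherwise.  Summing over pairs:

    LRF(T, T') = RF(T, T') + delta,

where RF is the plain Robinson-Foulds distance and delta counts
label-disjoint island pairs.  Everything here runs in O(n) overall via
Day's clade table (see :mod:`lrfdist.day_index`), and an explicit minimum
edit path can be produced and replayed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

from . import day_index
from .day_index import DayTable, GoodCladeMarks
from .tree_model import (
    LabeledTree,
    TreeError,
    labeled_isomorphic,
    prepare_pair,
)

__all__ = [
    "Island",
    "IslandPair",
    "IslandPairing",
    "LRFReport",
    "EditOp",
    "Del",
    "Ins",
    "Sub",
    "InvalidEditError",
    "extract_islands",
    "pair_islands",
    "island_lrf",
    "lrf_distance",
    "rf_distance",
    "compare_trees",
    "edit_path",
    "apply_edit",
    "apply_edit_path",
]

#: Pairing anchor of the island adjacent to the root leaf.
ROOT_ANCHOR = "ROOT"


# ---------------------------------------------------------------------------
# Islands
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Island:
    """A maximal bad-edge subtree, represented by its internal-node core.

    ``nodes`` lists the core internal nodes in postorder; all edges among
    them are bad, all boundary (terminal) edges are good.  ``epsilon`` is
    the number of internal bad edges (``len(nodes) - 1``); a star island has
    ``epsilon == 0``.  ``anchor`` is the shared identifier of the island's
    parent boundary edge (a good clade interval, or :data:`ROOT_ANCHOR` for
    the island next to the root leaf) used to match islands across trees.
    """

    nodes: tuple[int, ...]
    top: int
    anchor: Union[str, tuple[int, int]]
    labels: frozenset[str]
    terminal_leaves: frozenset[str]
    child_anchors: frozenset[tuple[int, int]]

    @property
    def epsilon(self) -> int:
        return len(self.nodes) - 1


def extract_islands(tree: LabeledTree, marks: GoodCladeMarks) -> list[Island]:
    """Partition a leaf-rooted tree's bad edges into islands (one traversal).

    Internal nodes joined by bad edges form the island cores; every internal
    node belongs to exactly one island.  Cores are returned in postorder of
    their topmost node.
    """
    root_leaf = tree.root
    start = marks.start_node
    parent: dict[int, Optional[int]] = {start: root_leaf}
    comp: dict[int, int] = {}  # node -> component representative (top node)
    order: list[int] = []
    for node, par in day_index._postorder(tree, start, root_leaf):
        if not tree.is_leaf(node):
            order.append(node)
        for c in tree.neighbors(node):
            if c != par:
                parent[c] = node
    # top-down pass: a node joins its parent's component over a bad edge
    members: dict[int, list[int]] = {}
    for node in reversed(order):  # reversed postorder = top-down
        par = parent[node]
        bad_parent_edge = (
            node != start
            and not tree.is_leaf(par)
            and not marks.good.get(node, False)
        )
        rep = comp[par] if bad_parent_edge else node
        comp[node] = rep
        members.setdefault(rep, []).append(node)

    po_index = {u: i for i, u in enumerate(order)}
    islands: list[Island] = []
    for node in order:  # postorder of top nodes keeps output deterministic
        if comp[node] != node:
            continue
        core_postorder = sorted(members[node], key=po_index.__getitem__)
        labels = frozenset(tree.label[u] for u in core_postorder)
        leaves = frozenset(
            tree.leaf_name[c]
            for u in core_postorder
            for c in tree.neighbors(u)
            if tree.is_leaf(c) and c != root_leaf
        )
        child_anchors = frozenset(
            marks.interval[c]
            for u in core_postorder
            for c in tree.neighbors(u)
            if not tree.is_leaf(c) and parent[c] == u and marks.good.get(c, False)
        )
        anchor: Union[str, tuple[int, int]]
        anchor = ROOT_ANCHOR if node == start else marks.interval[node]
        islands.append(
            Island(
                nodes=tuple(core_postorder),
                top=node,
                anchor=anchor,
                labels=labels,
                terminal_leaves=leaves,
                child_anchors=child_anchors,
            )
        )
    return islands


@dataclass(frozen=True)
class IslandPair:
    island1: Island
    island2: Island

    @property
    def shares_label(self) -> bool:
        return bool(self.island1.labels & self.island2.labels)

    @property
    def lrf(self) -> int:
        return island_lrf((self.island1, self.island2))


@dataclass(frozen=True)
class IslandPairing:
    """The one-to-one correspondence between islands of the two trees."""

    pairs: tuple[IslandPair, ...]

    @property
    def delta(self) -> int:
        return sum(1 for p in self.pairs if not p.shares_label)

    @property
    def rf(self) -> int:
        return sum(p.island1.epsilon + p.island2.epsilon for p in self.pairs)

    @property
    def lrf(self) -> int:
        return self.rf + self.delta


def pair_islands(islands1: Sequence[Island], islands2: Sequence[Island]) -> IslandPairing:
    """Match islands across trees through their shared parent boundary edge.

    Paired islands have identical terminal-edge bipartitions; the parent
    boundary edge (good clade interval, or the root-leaf edge) already
    determines the bijection.  A count mismatch indicates a bug upstream and
    raises rather than truncating.
    """
    if len(islands1) != len(islands2):
        raise AssertionError(
            f"island counts differ: {len(islands1)} vs {len(islands2)}"
        )
    by_anchor = {isl.anchor: isl for isl in islands2}
    if len(by_anchor) != len(islands2):
        raise AssertionError("duplicate island anchors")
    pairs = []
    for isl in islands1:
        if isl.anchor not in by_anchor:
            raise AssertionError(f"unmatched island anchor {isl.anchor!r}")
        pairs.append(IslandPair(isl, by_anchor[isl.anchor]))
    return IslandPairing(pairs=tuple(pairs))


def island_lrf(pair: tuple[Island, Island]) -> int:
    """Shortest labeled edit path length between two matched islands.

    ``eps + eps'`` when the islands share an internal-node label (reduce one
    island to a star around a shared-label node, then rebuild the other),
    plus one substitution when they are label-disjoint.
    """
    i1, i2 = pair
    extra = 0 if i1.labels & i2.labels else 1
    return i1.epsilon + i2.epsilon + extra


# ---------------------------------------------------------------------------
# Distances and report
# ---------------------------------------------------------------------------


@dataclass
class _Pipeline:
    p1: LabeledTree
    p2: LabeledTree
    table: DayTable
    marks1: GoodCladeMarks
    marks2: GoodCladeMarks
    pairing: IslandPairing


def _run_pipeline(
    t1: LabeledTree, t2: LabeledTree, unroot_mismatched: bool = False
) -> _Pipeline:
    p1, p2 = prepare_pair(t1, t2, unroot_mismatched=unroot_mismatched)
    table = day_index.build_table(p1)
    marks1, marks2, _ = day_index.find_good_clades(p2, table)
    islands1 = extract_islands(p1, marks1)
    islands2 = extract_islands(p2, marks2)
    pairing = pair_islands(islands1, islands2)
    return _Pipeline(p1, p2, table, marks1, marks2, pairing)


@dataclass
class LRFReport:
    """Full comparison: distances plus the per-island attribution."""

    lrf: int
    rf: int
    delta: int
    pairing: IslandPairing
    ops: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "lrf": self.lrf,
            "rf": self.rf,
            "delta": self.delta,
            "islands": [
                {
                    "epsilon_t1": p.island1.epsilon,
                    "epsilon_t2": p.island2.epsilon,
                    "labels_t1": sorted(p.island1.labels),
                    "labels_t2": sorted(p.island2.labels),
                    "label_disjoint": not p.shares_label,
                    "lrf": p.lrf,
                    "terminal_leaves_t1": sorted(p.island1.terminal_leaves),
                    "terminal_leaves_t2": sorted(p.island2.terminal_leaves),
                }
                for p in self.pairing.pairs
            ],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def compare_trees(
    t1: LabeledTree, t2: LabeledTree, unroot_mismatched: bool = False
) -> LRFReport:
    """Compute LRF, RF and delta with the per-island breakdown."""
    pipe = _run_pipeline(t1, t2, unroot_mismatched=unroot_mismatched)
    pairing = pipe.pairing
    return LRFReport(
        lrf=pairing.lrf,
        rf=pairing.rf,
        delta=pairing.delta,
        pairing=pairing,
        ops=dict(pipe.table.ops),
    )


def lrf_distance(
    t1: LabeledTree, t2: LabeledTree, unroot_mismatched: bool = False
) -> int:
    """Labeled Robinson-Foulds distance (= RF + delta)."""
    return compare_trees(t1, t2, unroot_mismatched=unroot_mismatched).lrf


def rf_distance(
    t1: LabeledTree, t2: LabeledTree, unroot_mismatched: bool = False
) -> int:
    """Plain Robinson-Foulds distance |B(T) \\ B(T')| + |B(T') \\ B(T)|.

    Computed from the same clade table: each tree's bad-edge count is its
    number of nontrivial clades minus the number of shared ones.
    """
    pipe = _run_pipeline(t1, t2, unroot_mismatched=unroot_mismatched)
    n_clades1 = len(pipe.table.node_row)
    n_clades2 = len(pipe.marks2.good)
    return (n_clades1 - pipe.marks1.n_good) + (n_clades2 - pipe.marks2.n_good)


# ---------------------------------------------------------------------------
# Edit operations
# ---------------------------------------------------------------------------


class InvalidEditError(TreeError):
    """An edit operation's preconditions do not hold on the given tree."""


@dataclass(frozen=True)
class Del:
    """Delete internal node ``x`` with respect to internal neighbor ``y``
    (contract the edge {x, y}; x's other neighbors attach to y)."""

    x: int
    y: int

    def to_dict(self) -> dict:
        return {"op": "del", "x": self.x, "y": self.y}


@dataclass(frozen=True)
class Ins:
    """Insert a new node as neighbor of ``y`` (degree >= 4), moving the
    neighbor subset ``moved`` (2 <= |moved| <= deg(y) - 2) to it; the new
    node receives ``label``.  ``new_id`` fixes the created node's id so
    recorded paths replay deterministically."""

    y: int
    moved: frozenset[int]
    label: str
    new_id: Optional[int] = None

    def to_dict(self) -> dict:
        return {
            "op": "ins",
            "y": self.y,
            "moved": sorted(self.moved),
            "label": self.label,
            "new_id": self.new_id,
        }


@dataclass(frozen=True)
class Sub:
    """Substitute the label of internal node ``x`` with ``label``."""

    x: int
    label: str

    def to_dict(self) -> dict:
        return {"op": "sub", "x": self.x, "label": self.label}


EditOp = Union[Del, Ins, Sub]


def _effective_degree(t: LabeledTree, u: int) -> int:
    # an internally-rooted tree's root carries a virtual dummy leaf, so its
    # degree in the unrooted reading is one higher
    extra = 1 if (t.rooted and u == t.root and not t.is_leaf(u)) else 0
    return t.degree(u) + extra


def _apply_inplace(t: LabeledTree, op: EditOp) -> None:
    if isinstance(op, Sub):
        if t.is_leaf(op.x) or op.x not in t._adj:
            raise InvalidEditError("Sub requires an internal node")
        t.set_label(op.x, op.label)
        return
    if isinstance(op, Del):
        x, y = op.x, op.y
        if x not in t._adj or t.is_leaf(x):
            raise InvalidEditError("Del requires an internal node x")
        if y not in t.neighbors(x) or t.is_leaf(y):
            raise InvalidEditError("Del requires an internal, non-leaf neighbor y")
        for z in list(t.neighbors(x)):
            if z != y:
                t.remove_edge(x, z)
                t.add_edge(y, z)
        t.remove_node(x)
        if t.root == x:
            t.root = y
        return
    if isinstance(op, Ins):
        y = op.y
        if y not in t._adj or t.is_leaf(y):
            raise InvalidEditError("Ins requires an internal node y")
        if _effective_degree(t, y) < 4:
            raise InvalidEditError("Ins requires a node of degree >= 4")
        moved = set(op.moved)
        if not moved <= t.neighbors(y):
            raise InvalidEditError("moved set must be a subset of y's neighbors")
        if len(moved) < 2 or len(moved) > _effective_degree(t, y) - 2:
            raise InvalidEditError(
                "moved set must satisfy 2 <= |Z| <= deg(y) - 2"
            )
        if op.new_id is None:
            x = t.new_node()
        else:
            if op.new_id in t._adj:
                raise InvalidEditError(f"node id {op.new_id} already in use")
            x = op.new_id
            t._adj[x] = set()
            t._next_id = max(t._next_id, x + 1)
        for z in moved:
            t.remove_edge(y, z)
            t.add_edge(x, z)
        t.add_edge(x, y)
        t.set_label(x, op.label)
        return
    raise TypeError(f"unknown edit op {op!r}")


def apply_edit(t: LabeledTree, op: EditOp) -> LabeledTree:
    """Apply one labeled node edit operation, returning a new tree.

    Preconditions (degree constraints) are checked; on internally-rooted
    trees the root counts one degree higher, matching the unrooted reading
    after dummy-leaf grafting, and insertions never displace the root.
    """
    out = t.copy()
    _apply_inplace(out, op)
    return out


def apply_edit_path(t1: LabeledTree, ops: Sequence[EditOp]) -> LabeledTree:
    """Replay an edit path produced by :func:`edit_path` on ``t1``.

    The path's node ids refer to the leaf-rooted normal form of ``t1``
    (deterministic), so the tree is normalized first; the result can be
    compared to the partner's normal form with :func:`labeled_isomorphic`.
    """
    from .tree_model import _prepare_single

    w = t1 if t1.leaf_rooted else _prepare_single(t1)
    w = w.copy()
    for op in ops:
        _apply_inplace(w, op)
    return w


# ---------------------------------------------------------------------------
# Explicit minimum edit path
# ---------------------------------------------------------------------------


def _collapse_order(tree: LabeledTree, core: Sequence[int], survivor: int):
    """Deletion schedule reducing an island core to ``survivor``.

    BFS from the survivor over core edges; deleting deepest-first keeps each
    node's deletion target alive.  Yields (node, target) pairs.
    """
    core_set = set(core)
    depth = {survivor: 0}
    bfs_parent: dict[int, int] = {}
    queue = [survivor]
    while queue:
        nxt: list[int] = []
        for u in queue:
            for v in sorted(tree.neighbors(u)):
                if v in core_set and v not in depth:
                    depth[v] = depth[u] + 1
                    bfs_parent[v] = u
                    nxt.append(v)
        queue = nxt
    for node in sorted(bfs_parent, key=lambda u: -depth[u]):
        yield node, bfs_parent[node]


def edit_path(
    t1: LabeledTree, t2: LabeledTree, unroot_mismatched: bool = False
) -> list[EditOp]:
    """Construct an explicit shortest edit path from ``t1`` to ``t2``.

    Per island pair: ``eps`` deletions reduce the source island to a star —
    around a node carrying a label shared with the partner island when one
    exists (first such node in postorder; deterministic) — then exactly one
    substitution for a label-disjoint pair, then ``eps'`` insertions with
    labels copied from the target island.  The total length equals
    ``lrf_distance(t1, t2)`` and replaying the path with
    :func:`apply_edit_path` yields a tree labeled-isomorphic to ``t2``'s
    normal form.
    """
    pipe = _run_pipeline(t1, t2, unroot_mismatched=unroot_mismatched)
    w = pipe.p1.copy()
    w2 = pipe.p2.copy()
    ops: list[EditOp] = []
    next_id = max(w._next_id, w2._next_id)

    centers: list[int] = []  # survivor node in w, per pair
    targets: list[int] = []  # surviving node in p2, per pair
    subs: list[tuple[int, str]] = []

    for pair in pipe.pairing.pairs:
        i1, i2 = pair.island1, pair.island2
        common = sorted(i1.labels & i2.labels)
        if common:
            lam = common[0]
            survivor = next(u for u in i1.nodes if pipe.p1.label[u] == lam)
            xprime = next(u for u in i2.nodes if pipe.p2.label[u] == lam)
        else:
            survivor = i1.nodes[0]
            xprime = i2.nodes[0]
            subs.append((survivor, pipe.p2.label[xprime]))
        for node, target in _collapse_order(w, i1.nodes, survivor):
            op = Del(x=node, y=target)
            ops.append(op)
            _apply_inplace(w, op)
        centers.append(survivor)
        targets.append(xprime)

    for x, lam in subs:
        op = Sub(x=x, label=lam)
        ops.append(op)
        _apply_inplace(w, op)

    # simulate the same reduction on the target's normal form, recording the
    # inverse insertions
    recorded: list[tuple[int, int, frozenset[int], str]] = []
    for pair, xprime in zip(pipe.pairing.pairs, targets):
        for node, target in _collapse_order(w2, pair.island2.nodes, xprime):
            zset = frozenset(z for z in w2.neighbors(node) if z != target)
            recorded.append((node, target, zset, w2.label[node]))
            _apply_inplace(w2, Del(x=node, y=target))

    # node correspondence between the two collapsed trees: leaves by name,
    # island centers by pair
    w_leaf = {name: u for u, name in w.leaf_name.items()}
    phi: dict[int, int] = {u: w_leaf[name] for u, name in w2.leaf_name.items()}
    for center, xprime in zip(centers, targets):
        phi[xprime] = center

    for node, target, zset, lam in reversed(recorded):
        op = Ins(
            y=phi[target],
            moved=frozenset(phi[z] for z in zset),
            label=lam,
            new_id=next_id,
        )
        ops.append(op)
        _apply_inplace(w, op)
        phi[node] = next_id
        next_id += 1

    return ops


def edit_path_to_json(ops: Sequence[EditOp]) -> str:
    """Serialize an edit path as a JSON list of tagged operations."""
    return json.dumps([op.to_dict() for op in ops])
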