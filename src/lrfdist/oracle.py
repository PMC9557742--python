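"""Independent brute-force references for testing the fast algorithms.

Nothing here shares code paths with :mod:`lrfdist.lrf_core`:
Robinson-Foulds is recomputed from explicitly enumerated bipartition sets,
and the labeled distance from an exhaustive shortest-path search in the
space of labeled trees under the three edit operations.  Intended for toy
instances only.
"""

from __future__ import annotations

import itertools
from collections import deque
from typing import Iterable, Iterator, Sequence

from .lrf_core import Del, Ins, Sub, apply_edit
from .tree_model import LabeledTree, canonical_form, prepare_pair

__all__ = [
    "rf_oracle",
    "lrf_oracle",
    "OracleSearchLimit",
    "bipartition_set",
    "edit_neighbors",
    "enumerate_labeled_trees",
]


class OracleSearchLimit(RuntimeError):
    """The uniform-cost search exceeded its cost cap without reaching the goal."""


# ---------------------------------------------------------------------------
# RF by explicit bipartition enumeration
# ---------------------------------------------------------------------------


def bipartition_set(prepared: LabeledTree) -> set[frozenset[frozenset[str]]]:
    """Nontrivial bipartitions of a leaf-rooted tree, enumerated explicitly."""
    all_names = frozenset(prepared.leaf_name.values())
    start = next(iter(prepared.neighbors(prepared.root)))
    below: dict[int, set[str]] = {}
    out: set[frozenset[frozenset[str]]] = set()
    for node, parent in _postorder(prepared, start, prepared.root):
        if prepared.is_leaf(node):
            below[node] = {prepared.leaf_name[node]}
            continue
        clade: set[str] = set()
        for c in prepared.neighbors(node):
            if c != parent:
                clade |= below[c]
        below[node] = clade
        if node == start:
            continue
        rest = all_names - clade
        if len(clade) >= 2 and len(rest) >= 2:
            out.add(frozenset({frozenset(clade), frozenset(rest)}))
    return out


def rf_oracle(t1: LabeledTree, t2: LabeledTree) -> int:
    """Robinson-Foulds distance by symmetric difference of bipartition sets."""
    p1, p2 = prepare_pair(t1, t2)
    b1, b2 = bipartition_set(p1), bipartition_set(p2)
    return len(b1 - b2) + len(b2 - b1)


# ---------------------------------------------------------------------------
# LRF by uniform-cost search over edit space
# ---------------------------------------------------------------------------


def edit_neighbors(
    tree: LabeledTree, labels: Iterable[str]
) -> Iterator[LabeledTree]:
    """All trees one labeled node edit away from ``tree``.

    ``labels`` is the allowed label alphabet for insertions and
    substitutions; drawing it from the union of the two compared trees'
    alphabets loses no shortest path, since an optimal island-by-island
    path never needs labels absent from both trees.
    """
    labels = sorted(set(labels))
    internals = tree.internal_nodes()
    # substitutions
    for x in internals:
        for lam in labels:
            if lam != tree.label[x]:
                yield apply_edit(tree, Sub(x=x, label=lam))
    # deletions: both orientations of every internal edge
    for x in internals:
        for y in tree.sorted_neighbors(x):
            if not tree.is_leaf(y):
                yield apply_edit(tree, Del(x=x, y=y))
    # insertions
    for y in internals:
        deg = tree.degree(y)
        if deg < 4:
            continue
        nbrs = tree.sorted_neighbors(y)
        for k in range(2, deg - 1):
            for zset in itertools.combinations(nbrs, k):
                for lam in labels:
                    yield apply_edit(tree, Ins(y=y, moved=frozenset(zset), label=lam))


def lrf_oracle(t1: LabeledTree, t2: LabeledTree, max_cost: int = 12) -> int:
    """Exact shortest edit-path length by uniform-cost (breadth-first) search.

    States are deduplicated by canonical form; expansion enumerates every
    legal deletion, insertion and substitution.  Raises
    :class:`OracleSearchLimit` beyond ``max_cost`` — small instances only
    (n <= 6 or so).
    """
    p1, p2 = prepare_pair(t1, t2)
    labels = sorted(p1.label_set() | p2.label_set())
    goal = canonical_form(p2)
    start_key = canonical_form(p1)
    if start_key == goal:
        return 0
    seen = {start_key}
    frontier: deque[tuple[LabeledTree, int]] = deque([(p1, 0)])
    while frontier:
        state, cost = frontier.popleft()
        if cost >= max_cost:
            raise OracleSearchLimit(f"no path of length <= {max_cost} found")
        for nxt in edit_neighbors(state, labels):
            key = canonical_form(nxt)
            if key in seen:
                continue
            if key == goal:
                return cost + 1
            seen.add(key)
            frontier.append((nxt, cost + 1))
    raise OracleSearchLimit("edit space exhausted without reaching the target")


# ---------------------------------------------------------------------------
# Exhaustive enumeration of small labeled tree spaces
# ---------------------------------------------------------------------------


def enumerate_labeled_trees(
    leaf_names: Sequence[str], labels: Sequence[str]
) -> list[LabeledTree]:
    """Every unrooted labeled tree on the given leaves (all topologies,
    binary and multifurcating, times all label assignments).

    For 5 leaves and 2 labels this yields 162 trees (15 binary + 10
    one-internal-edge + 1 star topology, with 8 / 4 / 2 labelings each).
    """
    leaf_names = sorted(leaf_names)
    labels = sorted(set(labels))
    if len(leaf_names) < 3:
        raise ValueError("need at least 3 leaves for an unrooted tree")

    # binary topologies by sequential leaf insertion on every edge
    def base() -> LabeledTree:
        t = LabeledTree()
        c = t.new_node()
        t.set_label(c, labels[0])
        for name in leaf_names[:3]:
            u = t.new_node()
            t.set_leaf(u, name)
            t.add_edge(c, u)
        return t

    topologies = [base()]
    for name in leaf_names[3:]:
        nxt = []
        for t in topologies:
            edges = {
                frozenset((u, v)) for u in t.nodes for v in t.neighbors(u)
            }
            for e in sorted(edges, key=sorted):
                u, v = sorted(e)
                s = t.copy()
                w = s.new_node()
                s.set_label(w, labels[0])
                s.remove_edge(u, v)
                s.add_edge(u, w)
                s.add_edge(w, v)
                leaf = s.new_node()
                s.set_leaf(leaf, name)
                s.add_edge(w, leaf)
                nxt.append(s)
        topologies = nxt

    # closure under internal-edge contraction gives the multifurcating shapes
    seen: dict[str, LabeledTree] = {}
    queue = list(topologies)
    while queue:
        t = queue.pop()
        key = canonical_form(t)
        if key in seen:
            continue
        seen[key] = t
        for x in t.internal_nodes():
            for y in t.sorted_neighbors(x):
                if not t.is_leaf(y) and y > x:
                    queue.append(apply_edit(t, Del(x=x, y=y)))

    out: list[LabeledTree] = []
    for key in sorted(seen):
        topo = seen[key]
        internals = topo.internal_nodes()
        for combo in itertools.product(labels, repeat=len(internals)):
            t = topo.copy()
            for u, lam in zip(internals, combo):
                t.set_label(u, lam)
            t.validate()
            out.append(t)
    return out


def _postorder(tree: LabeledTree, start: int, parent):
    stack = [(start, parent, False)]
    while stack:
        node, par, expanded = stack.pop()
        if expanded:
            yield node, par
            continue
        stack.append((node, par, True))
        for child in sorted(tree.neighbors(node), reverse=True):
            if child != par:
                stack.append((child, node, False))
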