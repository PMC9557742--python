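"""Day's linear-time clade index.

Leaves of the first tree are renumbered 1..n along a postorder traversal,
so that every clade becomes a contiguous interval of leaf numbers,
summarized by its endpoints ``[l, r]``.  Each nontrivial clade is stored in
an n-row table at row ``l`` or row ``r`` (at most one clade per row, a
placement Day showed is always possible), giving O(1) membership tests.
A second traversal, of the partner tree, marks the shared ("good") clades.

Elementary work is counted in ``DayTable.ops`` (node visits and table
writes) so that linear scaling can be asserted without wall-clock claims.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .tree_model import LabeledTree, LeafSetMismatchError, TreeError

__all__ = ["DayTable", "GoodCladeMarks", "build_table", "find_good_clades"]


@dataclass
class DayTable:
    """Postorder leaf numbering plus interval table for one tree."""

    n: int
    leaf_number: dict[str, int]
    row_l: list[int]
    row_r: list[int]
    row_good: list[bool]
    #: tree node -> (l, r) for every internal node (incl. the full-universe node)
    node_interval: dict[int, tuple[int, int]]
    #: tree node -> table row where its clade is stored
    node_row: dict[int, int]
    #: internal node adjacent to the root leaf (clade = all numbered leaves)
    start_node: int
    ops: dict[str, int] = field(default_factory=lambda: {"visits": 0, "writes": 0})

    def lookup(self, l: int, r: int) -> bool:
        """O(1) membership test for the clade summarized by [l, r]."""
        return (self.row_l[l] == l and self.row_r[l] == r) or (
            self.row_l[r] == l and self.row_r[r] == r
        )

    def mark_good(self, l: int, r: int) -> None:
        if self.row_l[l] == l and self.row_r[l] == r:
            self.row_good[l] = True
        elif self.row_l[r] == l and self.row_r[r] == r:
            self.row_good[r] = True
        else:  # pragma: no cover - guarded by lookup()
            raise KeyError((l, r))
        self.ops["writes"] += 1

    def stored_intervals(self) -> set[tuple[int, int]]:
        return {
            (self.row_l[i], self.row_r[i])
            for i in range(1, self.n + 1)
            if self.row_l[i] > 0
        }

    def dump_tsv(self) -> str:
        """Debug dump: one line per row (row, l, r, good)."""
        lines = ["row\tl\tr\tgood"]
        for i in range(1, self.n + 1):
            if self.row_l[i] > 0:
                lines.append(f"{i}\t{self.row_l[i]}\t{self.row_r[i]}\t{int(self.row_good[i])}")
            else:
                lines.append(f"{i}\t-\t-\t-")
        return "\n".join(lines)


@dataclass
class GoodCladeMarks:
    """Good/bad status of one tree's internal edges against the partner.

    ``good[u]`` refers to the edge above internal node ``u`` in the shared
    leaf-rooted orientation; the node adjacent to the root leaf (whose edge
    is terminal, hence good by definition) is excluded.  ``interval[u]``
    holds the shared clade id for good nodes.
    """

    good: dict[int, bool]
    interval: dict[int, tuple[int, int]]
    start_node: int
    n_good: int


def build_table(t1: LabeledTree) -> DayTable:
    """Index the nontrivial clades of a leaf-rooted tree in one traversal.

    Each internal node's clade is the interval of its leaves' postorder
    numbers; the interval is stored at row ``l`` when the node is the last
    child of its parent and at row ``r`` otherwise, which guarantees a free
    row.  The full-universe clade (trivial) is never stored.
    """
    if not t1.leaf_rooted:
        raise TreeError("build_table expects a leaf-rooted tree (see prepare_pair)")
    root_leaf = t1.root
    start = next(iter(t1.neighbors(root_leaf)))
    n = t1.n_leaves - 1
    leaf_number: dict[str, int] = {}
    row_l = [0] * (n + 1)
    row_r = [0] * (n + 1)
    row_good = [False] * (n + 1)
    node_interval: dict[int, tuple[int, int]] = {}
    node_row: dict[int, int] = {}
    ops = {"visits": 0, "writes": 0}

    # orientation prepass: parent of every node in the leaf-rooted view
    parent_map: dict[int, Optional[int]] = {start: root_leaf}
    stack = [start]
    while stack:
        u = stack.pop()
        for v in t1.neighbors(u):
            if v != parent_map[u]:
                parent_map[v] = u
                stack.append(v)

    span: dict[int, tuple[int, int]] = {}  # node -> (l, r)
    counter = 0
    for node, parent in _postorder(t1, start, root_leaf):
        ops["visits"] += 1
        if t1.is_leaf(node):
            counter += 1
            leaf_number[t1.leaf_name[node]] = counter
            span[node] = (counter, counter)
            continue
        kids = [c for c in t1.sorted_neighbors(node) if c != parent]
        l = min(span[c][0] for c in kids)
        r = max(span[c][1] for c in kids)
        span[node] = (l, r)
        node_interval[node] = (l, r)
        if node == start:
            continue  # universe clade: trivial, never stored
        # children are visited in ascending id order, so the last child of
        # ``parent`` is its largest neighbor other than parent's own parent
        last_child = max(c for c in t1.neighbors(parent) if c != parent_map[parent])
        row = l if node == last_child else r
        if row_l[row] != 0:  # pragma: no cover - excluded by Day's argument
            raise AssertionError(f"row {row} already occupied")
        row_l[row], row_r[row] = l, r
        node_row[node] = row
        ops["writes"] += 1

    return DayTable(
        n=n,
        leaf_number=leaf_number,
        row_l=row_l,
        row_r=row_r,
        row_good=row_good,
        node_interval=node_interval,
        node_row=node_row,
        start_node=start,
        ops=ops,
    )


def _postorder(t1: LabeledTree, start: int, parent: Optional[int]):
    stack: list[tuple[int, Optional[int], bool]] = [(start, parent, False)]
    while stack:
        node, par, expanded = stack.pop()
        if expanded:
            yield node, par
            continue
        stack.append((node, par, True))
        for child in sorted(t1.neighbors(node), reverse=True):
            if child != par:
                stack.append((child, node, False))


def find_good_clades(t2: LabeledTree, table: DayTable) -> tuple[GoodCladeMarks, GoodCladeMarks, int]:
    """Mark the clades of ``t2`` shared with the indexed tree.

    One bottom-up traversal computes (min, max, size) of each clade of
    ``t2`` under the partner's leaf numbering; a clade is good iff it is
    contiguous (``max - min + 1 == size``) and present in the table.
    Returns marks for the indexed tree, marks for ``t2`` and the count of
    shared nontrivial clades (good internal edges, identical for both trees).
    """
    if not t2.leaf_rooted:
        raise TreeError("find_good_clades expects a leaf-rooted tree")
    root_leaf = t2.root
    start = next(iter(t2.neighbors(root_leaf)))
    good2: dict[int, bool] = {}
    interval2: dict[int, tuple[int, int]] = {}
    agg: dict[int, tuple[int, int, int]] = {}  # node -> (min, max, size)
    n = table.n
    n_good = 0
    for node, parent in _postorder(t2, start, root_leaf):
        table.ops["visits"] += 1
        if t2.is_leaf(node):
            name = t2.leaf_name[node]
            if name not in table.leaf_number:
                raise LeafSetMismatchError(f"leaf {name!r} absent from the index")
            num = table.leaf_number[name]
            agg[node] = (num, num, 1)
            continue
        mn = mx = None
        size = 0
        for c in t2.neighbors(node):
            if c == parent:
                continue
            cmn, cmx, csz = agg[c]
            mn = cmn if mn is None or cmn < mn else mn
            mx = cmx if mx is None or cmx > mx else mx
            size += csz
        agg[node] = (mn, mx, size)
        if node == start:
            continue
        is_good = size == mx - mn + 1 and size <= n - 1 and table.lookup(mn, mx)
        good2[node] = is_good
        if is_good:
            interval2[node] = (mn, mx)
            table.mark_good(mn, mx)
            n_good += 1

    good1 = {
        node: table.row_good[table.node_row[node]]
        for node in table.node_row
    }
    interval1 = {node: table.node_interval[node] for node, g in good1.items() if g}
    marks1 = GoodCladeMarks(good=good1, interval=interval1, start_node=table.start_node, n_good=n_good)
    marks2 = GoodCladeMarks(good=good2, interval=interval2, start_node=start, n_good=n_good)
    return marks1, marks2, n_good
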