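"""Event-labeled phylogenetic trees: data model, Newick/NHX I/O, normalization.

The central object is :class:`LabeledTree`, an unordered tree on a leaf set
``L`` (gene identifiers) whose internal nodes each carry an *event label*
from a finite alphabet (typically ``speciation`` / ``duplication`` /
``transfer``, as produced by gene tree/species tree reconciliation).
Trees may be rooted or unrooted; after normalization every internal node has
degree >= 3 except the root of a rooted tree, which may have degree 2.

The comparison algorithms operate on a *leaf-rooted* normal form produced by
:func:`prepare_pair`: rooted inputs get a dummy leaf grafted at the root and
are re-rooted at that dummy; unrooted inputs are rooted at the
lexicographically smallest leaf.  Clades of the normal form are then in
bijection with the bipartitions of the input tree.
"""

from __future__ import annotations

import io
from typing import Iterable, Iterator, Optional

import dendropy

__all__ = [
    "LabeledTree",
    "LabelPolicy",
    "UNLABELED",
    "DUMMY_LEAF",
    "parse_tree",
    "write_tree",
    "prepare_pair",
    "labeled_isomorphic",
    "canonical_form",
    "TreeError",
    "NewickParseError",
    "DuplicateLeafNameError",
    "MissingLabelError",
    "LeafSetMismatchError",
    "RootednessMismatchError",
    "ReservedNameError",
]

#: Sentinel event label used when trees are loaded in unlabeled mode.
UNLABELED = "unlabeled"

#: Reserved leaf name grafted at the root of rooted inputs.  A collision with
#: a real leaf name is an error, never a silent rename.
DUMMY_LEAF = "__lrf_root__"

#: Recognized label policies for Newick I/O.
LabelPolicy = str
LABEL_POLICIES = ("name", "nhx", "none")

# NHX tag mapping (Ensembl-style duplication flags).
_NHX_CANONICAL = {"duplication": "D=Y", "speciation": "D=N", "transfer": "H=Y"}


class TreeError(ValueError):
    """Base class for labeled-tree errors."""


class NewickParseError(TreeError):
    pass


class DuplicateLeafNameError(TreeError):
    pass


class MissingLabelError(TreeError):
    pass


class LeafSetMismatchError(TreeError):
    pass


class RootednessMismatchError(TreeError):
    pass


class ReservedNameError(TreeError):
    pass


class LabeledTree:
    """Unordered tree with named leaves and event-labeled internal nodes.

    Nodes are opaque integer ids.  ``rooted`` distinguishes rooted trees
    (``root`` is an internal node of degree >= 2) from unrooted ones
    (``root is None``).  The leaf-rooted normal form used by the distance
    algorithms sets ``root`` to a *leaf* node; see :func:`prepare_pair`.
    """

    __slots__ = ("_adj", "leaf_name", "label", "rooted", "root", "_next_id")

    def __init__(self) -> None:
        self._adj: dict[int, set[int]] = {}
        self.leaf_name: dict[int, str] = {}
        self.label: dict[int, str] = {}
        self.rooted: bool = False
        self.root: Optional[int] = None
        self._next_id: int = 0

    # -- construction -----------------------------------------------------

    def new_node(self) -> int:
        nid = self._next_id
        self._next_id += 1
        self._adj[nid] = set()
        return nid

    def add_edge(self, u: int, v: int) -> None:
        self._adj[u].add(v)
        self._adj[v].add(u)

    def remove_edge(self, u: int, v: int) -> None:
        self._adj[u].discard(v)
        self._adj[v].discard(u)

    def remove_node(self, u: int) -> None:
        for v in list(self._adj[u]):
            self.remove_edge(u, v)
        del self._adj[u]
        self.leaf_name.pop(u, None)
        self.label.pop(u, None)

    def set_leaf(self, u: int, name: str) -> None:
        self.leaf_name[u] = name

    def set_label(self, u: int, lab: str) -> None:
        self.label[u] = lab

    # -- queries ----------------------------------------------------------

    @property
    def nodes(self) -> Iterable[int]:
        return self._adj.keys()

    def neighbors(self, u: int) -> set[int]:
        return self._adj[u]

    def sorted_neighbors(self, u: int) -> list[int]:
        return sorted(self._adj[u])

    def degree(self, u: int) -> int:
        return len(self._adj[u])

    def is_leaf(self, u: int) -> bool:
        return u in self.leaf_name

    def leaves(self) -> list[int]:
        return sorted(self.leaf_name)

    def leaf_names(self) -> set[str]:
        return set(self.leaf_name.values())

    def internal_nodes(self) -> list[int]:
        return sorted(u for u in self._adj if u not in self.leaf_name)

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_name)

    def label_set(self) -> set[str]:
        return set(self.label.values())

    @property
    def leaf_rooted(self) -> bool:
        """True for the normal form rooted at a leaf (Day-style rooting)."""
        return self.rooted and self.root is not None and self.is_leaf(self.root)

    def copy(self) -> "LabeledTree":
        t = LabeledTree()
        t._adj = {u: set(vs) for u, vs in self._adj.items()}
        t.leaf_name = dict(self.leaf_name)
        t.label = dict(self.label)
        t.rooted = self.rooted
        t.root = self.root
        t._next_id = self._next_id
        return t

    # -- traversal --------------------------------------------------------

    def postorder(self, start: Optional[int] = None) -> list[tuple[int, Optional[int]]]:
        """Iterative postorder as (node, parent) pairs, children in id order.

        For rooted trees the traversal starts at the root; a leaf root is
        emitted last with its single child traversed first.  For unrooted
        trees a ``start`` node must be given.
        """
        if start is None:
            if self.root is None:
                raise TreeError("postorder on an unrooted tree needs a start node")
            start = self.root
        out: list[tuple[int, Optional[int]]] = []
        stack: list[tuple[int, Optional[int], bool]] = [(start, None, False)]
        while stack:
            node, parent, expanded = stack.pop()
            if expanded:
                out.append((node, parent))
                continue
            stack.append((node, parent, True))
            for child in sorted(self._adj[node], reverse=True):
                if child != parent:
                    stack.append((child, node, False))
        return out

    # -- normalization & validation ---------------------------------------

    def suppress_degree_two(self) -> None:
        """Contract internal non-root nodes of degree 2 (in place)."""
        for u in list(self._adj):
            if u in self.leaf_name or u == self.root:
                continue
            if len(self._adj[u]) == 2:
                a, b = sorted(self._adj[u])
                self.remove_node(u)
                self.add_edge(a, b)

    def unroot(self) -> None:
        """Drop rooting; a degree-2 root is suppressed."""
        if not self.rooted:
            return
        root = self.root
        self.rooted = False
        self.root = None
        if root is not None and root in self._adj and not self.is_leaf(root):
            if len(self._adj[root]) == 2:
                a, b = sorted(self._adj[root])
                self.remove_node(root)
                self.add_edge(a, b)

    def validate(self) -> None:
        if self.n_leaves < 2:
            raise TreeError("a tree needs at least 2 leaves")
        names = list(self.leaf_name.values())
        if len(set(names)) != len(names):
            raise DuplicateLeafNameError("duplicate leaf names")
        for u in self._adj:
            deg = len(self._adj[u])
            if u in self.leaf_name:
                if deg != 1:
                    raise TreeError(f"leaf {self.leaf_name[u]!r} has degree {deg}")
            else:
                if u not in self.label:
                    raise MissingLabelError(f"internal node {u} has no label")
                min_deg = 2 if (self.rooted and u == self.root) else 3
                if deg < min_deg:
                    raise TreeError(f"internal node {u} has degree {deg} < {min_deg}")
        if self.rooted and (self.root is None or self.root not in self._adj):
            raise TreeError("rooted tree without a valid root")
        # connectivity
        nodes = list(self._adj)
        seen = {nodes[0]}
        stack = [nodes[0]]
        while stack:
            u = stack.pop()
            for v in self._adj[u]:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        if len(seen) != len(nodes):
            raise TreeError("tree is not connected")

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "rooted" if self.rooted else "unrooted"
        return f"<LabeledTree {kind} n_leaves={self.n_leaves}>"


# ---------------------------------------------------------------------------
# Newick / NHX I/O (via dendropy)
# ---------------------------------------------------------------------------


def _nhx_label(comments: list[str]) -> Optional[str]:
    """Extract an event label from a node's NHX comment strings."""
    for comment in comments:
        if not comment.startswith("&&NHX"):
            continue
        tags: dict[str, str] = {}
        for field in comment[5:].strip(":").split(":"):
            if "=" in field:
                key, _, value = field.partition("=")
                tags[key.strip().upper()] = value.strip().upper()
        if tags.get("H") == "Y" or tags.get("T") == "Y":
            return "transfer"
        if tags.get("D") == "Y":
            return "duplication"
        if tags.get("D") == "N":
            return "speciation"
    return None


def parse_tree(
    text: str,
    label_policy: LabelPolicy = "name",
    rooted: Optional[bool] = None,
) -> LabeledTree:
    """Parse a Newick/NHX string into a validated :class:`LabeledTree`.

    ``label_policy`` selects where internal event labels live:

    - ``"name"``: the internal node's Newick name is the label;
    - ``"nhx"``: NHX comment tags (``D=Y`` duplication, ``D=N`` speciation,
      ``H=Y``/``T=Y`` transfer);
    - ``"none"``: unlabeled mode; every internal node gets the sentinel
      :data:`UNLABELED`, under which the labeled distance collapses to
      plain Robinson-Foulds.

    Rootedness is taken from ``rooted`` when given, else from a ``[&R]``/
    ``[&U]`` hint, else inferred: a basal bifurcation reads as rooted.
    Branch lengths are parsed and ignored (the distances are topological);
    degree-2 non-root internal nodes are suppressed.
    """
    if label_policy not in LABEL_POLICIES:
        raise ValueError(f"unknown label policy {label_policy!r}")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
            extract_comment_metadata=False,
        )
    except Exception as exc:  # dendropy raises assorted error types
        if "DuplicateTaxon" in type(exc).__name__:
            raise DuplicateLeafNameError(f"duplicate leaf name: {exc}") from exc
        raise NewickParseError(f"malformed Newick: {exc}") from exc

    tree = LabeledTree()
    node_id: dict[int, int] = {}
    seen_names: set[str] = set()
    for nd in dtree.preorder_node_iter():
        nid = tree.new_node()
        node_id[id(nd)] = nid
        if nd.parent_node is not None:
            tree.add_edge(node_id[id(nd.parent_node)], nid)
        if nd.is_leaf():
            name = nd.taxon.label if nd.taxon is not None else nd.label
            if not name:
                raise NewickParseError("leaf without a name")
            if name in seen_names:
                raise DuplicateLeafNameError(f"duplicate leaf name {name!r}")
            seen_names.add(name)
            tree.set_leaf(nid, name)
        else:
            if label_policy == "name":
                if not nd.label:
                    raise MissingLabelError(
                        "internal node without a name under label policy 'name'"
                    )
                tree.set_label(nid, nd.label.strip().lower())
            elif label_policy == "nhx":
                lab = _nhx_label(nd.comments)
                if lab is None:
                    raise MissingLabelError(
                        "internal node without an NHX event tag under policy 'nhx'"
                    )
                tree.set_label(nid, lab)
            else:
                tree.set_label(nid, UNLABELED)

    seed = node_id[id(dtree.seed_node)]
    if rooted is None:
        if dtree.is_rooted is not None:
            rooted = bool(dtree.is_rooted)
        else:
            rooted = tree.degree(seed) == 2
    tree.rooted = rooted
    tree.root = seed if rooted else None
    if not rooted and not tree.is_leaf(seed) and tree.degree(seed) == 2:
        # basal bifurcation declared unrooted: suppress the spurious seed
        a, b = sorted(tree.neighbors(seed))
        tree.remove_node(seed)
        tree.add_edge(a, b)
    tree.suppress_degree_two()
    tree.validate()
    return tree


def write_tree(tree: LabeledTree, label_policy: LabelPolicy = "name") -> str:
    """Serialize a tree to Newick/NHX text.

    ``parse_tree(write_tree(t), policy)`` is labeled-isomorphic to ``t``.
    Leaf-rooted normal forms are written as unrooted trees (the rooting is
    an algorithmic device, not part of the tree's meaning).
    """
    if label_policy not in LABEL_POLICIES:
        raise ValueError(f"unknown label policy {label_policy!r}")
    taxa = dendropy.TaxonNamespace()
    dtree = dendropy.Tree(taxon_namespace=taxa)

    if tree.rooted and not tree.leaf_rooted:
        start = tree.root
        as_rooted = True
    else:
        internals = tree.internal_nodes()
        if not internals:
            # bare cherry written as rooted pair
            start = None
            as_rooted = True
        else:
            start = internals[0]
            as_rooted = False

    def decorate(dnode: dendropy.Node, u: int) -> None:
        if tree.is_leaf(u):
            dnode.taxon = taxa.new_taxon(tree.leaf_name[u])
            return
        lab = tree.label[u]
        if label_policy == "name":
            dnode.label = lab
        elif label_policy == "nhx":
            if lab not in _NHX_CANONICAL:
                raise TreeError(
                    f"label {lab!r} has no NHX encoding; use label policy 'name'"
                )
            dnode.comments.append("&&NHX:" + _NHX_CANONICAL[lab])

    if start is None:  # two leaves, no internal node (not produced by parse)
        for u in tree.leaves():
            child = dendropy.Node()
            decorate(child, u)
            dtree.seed_node.add_child(child)
    else:
        dnodes = {start: dtree.seed_node}
        decorate(dtree.seed_node, start)
        stack = [(start, None)]
        while stack:
            u, parent = stack.pop()
            for v in tree.sorted_neighbors(u):
                if v == parent:
                    continue
                dn = dendropy.Node()
                decorate(dn, v)
                dnodes[u].add_child(dn)
                dnodes[v] = dn
                stack.append((v, u))

    dtree.is_rooted = as_rooted
    out = io.StringIO()
    dtree.write(
        file=out,
        schema="newick",
        unquoted_underscores=True,
        suppress_rooting=False,
        suppress_item_comments=False,
    )
    return out.getvalue().strip()


# ---------------------------------------------------------------------------
# Pair normalization and isomorphism
# ---------------------------------------------------------------------------


def _prepare_single(t: LabeledTree) -> LabeledTree:
    """Leaf-rooted normal form of one tree (see :func:`prepare_pair`)."""
    p = t.copy()
    if p.rooted:
        if p.leaf_rooted:
            return p
        if DUMMY_LEAF in p.leaf_names():
            raise ReservedNameError(f"reserved leaf name {DUMMY_LEAF!r} present in input")
        dummy = p.new_node()
        p.set_leaf(dummy, DUMMY_LEAF)
        p.add_edge(dummy, p.root)
        p.root = dummy
    else:
        name_to_node = {name: u for u, name in p.leaf_name.items()}
        p.root = name_to_node[min(name_to_node)]
        p.rooted = True
    return p


def prepare_pair(
    t1: LabeledTree, t2: LabeledTree, unroot_mismatched: bool = False
) -> tuple[LabeledTree, LabeledTree]:
    """Normalize a tree pair for the clade-table algorithm.

    Both trees must share the same leaf set and rootedness.  Rooted inputs
    get the dummy leaf :data:`DUMMY_LEAF` grafted at the root and are
    re-rooted there; unrooted inputs are both rooted at the lexicographically
    smallest leaf.  Either way the outputs are leaf-rooted trees whose
    nontrivial clades are in bijection with the inputs' nontrivial
    bipartitions.  ``unroot_mismatched=True`` resolves a rooted/unrooted
    mixture by unrooting both.
    """
    names1, names2 = t1.leaf_names(), t2.leaf_names()
    if names1 != names2:
        only1 = sorted(names1 - names2)
        only2 = sorted(names2 - names1)
        raise LeafSetMismatchError(
            f"leaf sets differ: only in first {only1}; only in second {only2}"
        )
    if t1.rooted != t2.rooted:
        if not unroot_mismatched:
            raise RootednessMismatchError(
                "one tree is rooted and the other unrooted; pass "
                "unroot_mismatched=True to compare them as unrooted trees"
            )
        t1, t2 = t1.copy(), t2.copy()
        t1.unroot()
        t2.unroot()
    p1, p2 = _prepare_single(t1), _prepare_single(t2)
    p1.validate()
    p2.validate()
    return p1, p2


def canonical_form(tree: LabeledTree) -> str:
    """Rooting-normalized canonical encoding; equal iff labeled-isomorphic.

    Children encodings are sorted, labels included.  Unrooted trees and
    leaf-rooted normal forms are encoded from the (lexicographically
    smallest / designated) root leaf; internally rooted trees from the root.
    """
    if tree.rooted and not tree.leaf_rooted:
        start, parent0 = tree.root, None
        prefix = "R"
    else:
        if tree.leaf_rooted:
            leaf = tree.root
        else:
            name_to_node = {name: u for u, name in tree.leaf_name.items()}
            leaf = name_to_node[min(name_to_node)]
        start = next(iter(tree.neighbors(leaf)))
        parent0 = leaf
        prefix = f"U[{tree.leaf_name[leaf]}]"
    enc: dict[int, str] = {}
    for node, parent in tree.postorder(start) if parent0 is None else _postorder_from(
        tree, start, parent0
    ):
        if tree.is_leaf(node):
            enc[node] = "L" + tree.leaf_name[node]
        else:
            kids = sorted(enc[c] for c in tree.neighbors(node) if c != parent)
            enc[node] = "(" + tree.label[node] + "|" + ",".join(kids) + ")"
    return prefix + enc[start]


def _postorder_from(
    tree: LabeledTree, start: int, parent: Optional[int]
) -> Iterator[tuple[int, Optional[int]]]:
    stack: list[tuple[int, Optional[int], bool]] = [(start, parent, False)]
    while stack:
        node, par, expanded = stack.pop()
        if expanded:
            yield node, par
            continue
        stack.append((node, par, True))
        for child in sorted(tree.neighbors(node), reverse=True):
            if child != par:
                stack.append((child, node, False))


def labeled_isomorphic(t1: LabeledTree, t2: LabeledTree) -> bool:
    """True iff a node bijection preserves adjacency, leaf names and labels."""
    if t1.leaf_names() != t2.leaf_names():
        return False
    if t1.rooted != t2.rooted or t1.leaf_rooted != t2.leaf_rooted:
        return False
    return canonical_form(t1) == canonical_form(t2)
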