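"""Random labeled trees and the random-edit perturbation protocol.

The perturbation protocol mirrors the simulation used to benchmark the
labeled distance against the plain topological one: at each step, with
probability ``p_sub`` (default 0.3) the label of one random internal node is
substituted; the remaining probability mass is spread evenly over all
candidate topological moves — every internal edge (a potential node
deletion) and every node of degree > 3 (a potential node insertion).  When
one move class has no candidates its mass goes to the other.  Everything is
driven by an explicit seed and is bit-reproducible.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from math import comb
from typing import Optional, Sequence

import pandas as pd

from .lrf_core import Del, EditOp, Ins, Sub, apply_edit, compare_trees
from .tree_model import LabeledTree, TreeError

__all__ = [
    "PerturbationConfig",
    "NoLegalEditError",
    "random_labeled_tree",
    "random_edit",
    "perturb",
    "edit_distance_experiment",
]

DEFAULT_LABELS = ("speciation", "duplication")


class NoLegalEditError(TreeError):
    """No edit operation is legal on this tree (e.g. star tree, one label)."""


@dataclass
class PerturbationConfig:
    """Parameters of the random-edit protocol.

    ``p_sub`` is the per-edit probability of a label substitution;
    ``labels`` the alphabet (defaults to the tree's own label set).
    """

    p_sub: float = 0.3
    labels: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_sub <= 1.0:
            raise ValueError("p_sub must be in [0, 1]")


def random_labeled_tree(
    n: int,
    labels: Sequence[str] = DEFAULT_LABELS,
    seed: Optional[int] = None,
    shape: str = "binary",
    rng: Optional[random.Random] = None,
    contraction_p: float = 0.25,
) -> LabeledTree:
    """Random rooted labeled tree on ``n`` leaves, deterministic given seed.

    Topology by sequential random leaf attachment (each new leaf subdivides
    a uniformly chosen edge); ``shape="multifurcating"`` additionally
    contracts each internal edge independently with probability
    ``contraction_p``.  Internal labels are i.i.d. uniform over ``labels``.
    Leaf names are ``t001, t002, ...`` (zero-padded, so lexicographic and
    numeric order agree).  Everything is iterative: trees with tens of
    thousands of leaves are fine.
    """
    if n < 2:
        raise ValueError("need at least 2 leaves")
    if not labels:
        raise ValueError("label set must be nonempty")
    if shape not in ("binary", "multifurcating"):
        raise ValueError(f"unknown shape {shape!r}")
    rng = rng if rng is not None else random.Random(seed)
    labels = list(labels)
    width = max(3, len(str(n)))
    names = [f"t{i + 1:0{width}d}" for i in range(n)]

    t = LabeledTree()
    t.rooted = True
    root = t.new_node()
    t.root = root
    parent: dict[int, int] = {}
    edges: list[tuple[int, int]] = []  # (parent, child) pairs
    for name in names[:2]:
        u = t.new_node()
        t.set_leaf(u, name)
        t.add_edge(root, u)
        parent[u] = root
        edges.append((root, u))
    for name in names[2:]:
        idx = rng.randrange(len(edges))
        u, v = edges[idx]
        w = t.new_node()
        t.remove_edge(u, v)
        t.add_edge(u, w)
        t.add_edge(w, v)
        leaf = t.new_node()
        t.set_leaf(leaf, name)
        t.add_edge(w, leaf)
        parent[w], parent[v], parent[leaf] = u, w, w
        edges[idx] = (u, w)
        edges.append((w, v))
        edges.append((w, leaf))

    if shape == "multifurcating":
        for v in t.internal_nodes():
            if v == root or rng.random() >= contraction_p:
                continue
            p0 = parent[v]
            for z in list(t.neighbors(v)):
                if z != p0:
                    t.remove_edge(v, z)
                    t.add_edge(p0, z)
                    parent[z] = p0
            t.remove_node(v)

    for node in t.internal_nodes():
        t.set_label(node, labels[rng.randrange(len(labels))])
    t.validate()
    return t


def _effective_degree(t: LabeledTree, u: int) -> int:
    return t.degree(u) + (1 if (t.rooted and u == t.root and not t.is_leaf(u)) else 0)


def _draw_edit(t: LabeledTree, config: PerturbationConfig, rng: random.Random) -> EditOp:
    labels = sorted(set(config.labels) if config.labels else t.label_set())
    internals = t.internal_nodes()
    if not internals:
        raise NoLegalEditError("tree has no internal node")

    sub_possible = len(labels) >= 2
    del_candidates = [
        (x, y)
        for x in internals
        for y in t.sorted_neighbors(x)
        if y > x and not t.is_leaf(y)
    ]
    ins_candidates = [y for y in internals if _effective_degree(t, y) > 3]
    topo = [("del", c) for c in del_candidates] + [("ins", c) for c in ins_candidates]

    if sub_possible and topo:
        do_sub = rng.random() < config.p_sub
    elif sub_possible:
        do_sub = True
    elif topo:
        do_sub = False
    else:
        raise NoLegalEditError("no legal edit: star tree with a single label")

    if do_sub:
        x = internals[rng.randrange(len(internals))]
        choices = [lam for lam in labels if lam != t.label[x]]
        return Sub(x=x, label=choices[rng.randrange(len(choices))])

    kind, cand = topo[rng.randrange(len(topo))]
    if kind == "del":
        u, v = cand
        # the two orientations of a contraction are equivalent; the surviving
        # endpoint is chosen uniformly
        return Del(x=u, y=v) if rng.random() < 0.5 else Del(x=v, y=u)
    y = cand
    pool = t.sorted_neighbors(y)
    dmax = _effective_degree(t, y) - 2
    sizes = list(range(2, dmax + 1))
    weights = [comb(len(pool), k) for k in sizes]
    k = rng.choices(sizes, weights=weights)[0]
    moved = frozenset(rng.sample(pool, k))
    return Ins(y=y, moved=moved, label=labels[rng.randrange(len(labels))])


def random_edit(
    t: LabeledTree,
    config: Optional[PerturbationConfig] = None,
    rng: Optional[random.Random] = None,
    seed: Optional[int] = None,
) -> tuple[LabeledTree, EditOp]:
    """Draw one legal random edit and apply it, returning (tree, op)."""
    config = config or PerturbationConfig()
    rng = rng if rng is not None else random.Random(seed)
    op = _draw_edit(t, config, rng)
    return apply_edit(t, op), op


def perturb(
    t: LabeledTree,
    k: int,
    config: Optional[PerturbationConfig] = None,
    seed: Optional[int] = None,
    rng: Optional[random.Random] = None,
) -> tuple[LabeledTree, list[EditOp]]:
    """Apply ``k`` sequential random edits; returns the edited tree and the
    replayable operation list.  The labeled distance from the original tree
    to the result is at most ``k`` (each op moves the distance by <= 1)."""
    if k < 0:
        raise ValueError("k must be >= 0")
    config = config or PerturbationConfig()
    rng = rng if rng is not None else random.Random(seed)
    ops: list[EditOp] = []
    for _ in range(k):
        t, op = random_edit(t, config=config, rng=rng)
        ops.append(op)
    return t, ops


def edit_distance_experiment(
    tree: LabeledTree,
    ks: Sequence[int],
    replicates: int = 10,
    config: Optional[PerturbationConfig] = None,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Distance-vs-edits experiment: perturb ``tree`` by k random edits and
    measure RF/LRF back to the original, over replicates.

    Returns a DataFrame with columns (replicate, k, rf, lrf, delta) — the
    CSV schema of the command-line runner.
    """
    config = config or PerturbationConfig()
    rows = []
    base = random.Random(seed)
    for rep in range(replicates):
        for k in ks:
            rng = random.Random(base.randrange(2**31))
            edited, _ = perturb(tree, k, config=config, rng=rng)
            report = compare_trees(tree, edited)
            rows.append(
                {
                    "replicate": rep,
                    "k": k,
                    "rf": report.rf,
                    "lrf": report.lrf,
                    "delta": report.delta,
                }
            )
    return pd.DataFrame(rows)
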