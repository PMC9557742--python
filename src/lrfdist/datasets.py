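"""Built-in example trees.

:func:`worked_example_pair` returns the small rooted gene-tree pair used
throughout the documentation and tests: eight genes (A, B, C, D, E, F, I, J)
with a binary speciation/duplication labeling.  Compared against each other,
the two trees decompose into exactly four island pairs whose shortest
labeled edit paths have lengths 6, 0, 1 and 0:

- the island spanning the backbone around D, I and J has three bad internal
  edges in the first tree and two in the second, and the two sides share no
  label (all speciation vs. all duplication): 3 + 2 + 1 = 6 edits;
- the (A,B) cherry is a star island with matching labels: 0 edits;
- the node grouping (A,B) with C is a star island whose labels differ
  (speciation vs. duplication): a single substitution;
- the (E,F) cherry matches exactly: 0 edits.

Hence LRF = 7, of which RF = 5 (bad edges) and delta = 2 (label-disjoint
island pairs).
"""

from __future__ import annotations

from .tree_model import LabeledTree, parse_tree

__all__ = ["WORKED_EXAMPLE_NEWICK_1", "WORKED_EXAMPLE_NEWICK_2", "worked_example_pair"]

WORKED_EXAMPLE_NEWICK_1 = (
    "(((A,B)speciation,C)speciation,"
    "(((E,F)speciation,D)speciation,(I,J)speciation)speciation)speciation;"
)

WORKED_EXAMPLE_NEWICK_2 = (
    "(((A,B)speciation,C)duplication,"
    "(((E,F)speciation,I)duplication,J)duplication,D)duplication;"
)


def worked_example_pair() -> tuple[LabeledTree, LabeledTree]:
    """The rooted 8-leaf worked-example tree pair (see module docstring)."""
    t1 = parse_tree(WORKED_EXAMPLE_NEWICK_1, label_policy="name", rooted=True)
    t2 = parse_tree(WORKED_EXAMPLE_NEWICK_2, label_policy="name", rooted=True)
    return t1, t2
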