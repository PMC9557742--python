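"""Produce an explicit minimum edit path and replay it.

The distance is not just a number: a concrete shortest sequence of node
deletions, insertions and label substitutions can be constructed and
replayed, ending at a tree labeled-isomorphic to the target.
"""

from lrfdist import (
    apply_edit_path,
    edit_path,
    labeled_isomorphic,
    lrf_distance,
    worked_example_pair,
)
from lrfdist.tree_model import _prepare_single

t1, t2 = worked_example_pair()
ops = edit_path(t1, t2)

print(f"minimum edit path ({len(ops)} operations, = LRF {lrf_distance(t1, t2)}):")
for op in ops:
    print(f"  {op.to_dict()}")

result = apply_edit_path(t1, ops)
print("replay reaches the target tree:", labeled_isomorphic(result, _prepare_single(t2)))
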