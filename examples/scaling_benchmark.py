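"""Linear scaling of the distance computation.

Counts the elementary work (tree-node visits and clade-table writes) done
while comparing random tree pairs of growing size, and fits a line: the
algorithm does a constant amount of table work per leaf.  Wall-clock time
is printed for information.
"""

import time

import numpy as np

from lrfdist import compare_trees, random_labeled_tree

sizes = [100, 1000, 10000]
mean_ops = []
print("n\tops\tseconds")
for n in sizes:
    t1 = random_labeled_tree(n, seed=2 * n)
    t2 = random_labeled_tree(n, seed=2 * n + 1)
    t0 = time.perf_counter()
    report = compare_trees(t1, t2)
    elapsed = time.perf_counter() - t0
    ops = sum(report.ops.values())
    mean_ops.append(ops)
    print(f"{n}\t{ops}\t{elapsed:.3f}")

x, y = np.asarray(sizes, float), np.asarray(mean_ops, float)
slope, intercept = np.polyfit(x, y, 1)
resid = y - (slope * x + intercept)
r2 = 1 - float(resid @ resid) / float(((y - y.mean()) ** 2).sum())
print(f"linear fit: ops ~ {slope:.2f} n + {intercept:.0f}  (R^2 = {r2:.6f})")
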