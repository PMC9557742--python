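"""Distance versus number of random edits.

Perturbs a random 50-leaf labeled tree with k random edits (30% label
substitutions, the rest spread evenly over candidate deletions and
insertions) and measures RF and LRF back to the original.  LRF never
exceeds k (it is a minimum path length) and tracks k closely while k is
small; RF sits lower because it ignores the labels.
"""

from lrfdist import edit_distance_experiment, random_labeled_tree

tree = random_labeled_tree(50, seed=404, shape="binary")
df = edit_distance_experiment(tree, ks=range(1, 26, 4), replicates=10, seed=0)

summary = df.groupby("k")[["rf", "lrf"]].mean()
print("mean distance over 10 replicates per k:")
print(summary.round(2).to_string())
print()
print("LRF <= k in every replicate:", bool((df.lrf <= df.k).all()))
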