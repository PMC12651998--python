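"""Simulate a small benchmark suite and inspect its properties.

Builds random sparse TF->target networks with matched steady-state
expression (100 cells each) and prints the topology statistics the
simulator guarantees: gene counts, edge counts in [n, 2n], TF-only
sources, and the dropout fraction of the expression layer.
"""

import numpy as np

import planet

cfg = planet.SimConfig(n_min=15, n_max=30, tf_fraction=0.3, n_cells=100)
train_pairs, test_pairs = planet.make_benchmark_suite(cfg, n_train=5,
                                                      n_test=2, seed=1)

print(f"{'split':<6} {'genes':>5} {'TFs':>4} {'edges':>6} {'zeros':>6}")
for split, pairs in (("train", train_pairs), ("test", test_pairs)):
    for grn, expr in pairs:
        zeros = (expr.values == 0).mean()
        print(f"{split:<6} {grn.n_genes:>5} {int(grn.tf_mask.sum()):>4} "
              f"{grn.n_edges:>6} {zeros:>6.2f}")

# edge counts sit inside [n, 2n]; zeros reflect the dropout layer that
# mimics scRNA-seq sparsity.
grn, expr = train_pairs[0]
print("\nfirst network edge list (first 5):", grn.edge_list()[:5])
print("expression matrix shape (cells x genes):", expr.values.shape)
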