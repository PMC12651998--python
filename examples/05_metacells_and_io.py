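"""File round-trips and metacell aggregation.

Writes a simulated suite to disk in the package's plain-text formats
(CSV expression, TSV edge lists, TSV gene roles), reads it back, and
aggregates cells into metacells to combat dropout before inference.
"""

import tempfile
from pathlib import Path

import numpy as np

import planet

sim = planet.SimConfig(n_min=10, n_max=10, n_cells=60)
grn = planet.sample_grn_topology(sim, seed=4)
expr = planet.simulate_expression(grn, sim, seed=5)

with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    planet.write_expression(expr, tmp / "expr.csv")
    planet.write_edges(grn, tmp / "edges.tsv")
    planet.write_gene_roles(grn, tmp / "roles.tsv")

    genes, tf_mask = planet.read_gene_roles(tmp / "roles.tsv")
    back = planet.read_expression(tmp / "expr.csv")   # canonical gene order
    net = planet.read_edges(tmp / "edges.tsv", genes, tf_mask)
    print("round-trip edges preserved:", net.n_edges == grn.n_edges)
    print("expression max abs diff:",
          float(np.abs(back.reorder(expr.genes).values - expr.values).max()))

agg = planet.metacell_aggregate(expr, n_metacells=12, seed=0)
print(f"aggregated {expr.n_cells} cells -> {agg.n_cells} metacells")
print(f"dropout fraction: cells {(expr.values == 0).mean():.2f} -> "
      f"metacells {(agg.values == 0).mean():.2f}")
# averaging similar cells fills in zeros, the point of metacell pooling.
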