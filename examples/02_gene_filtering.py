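"""Rank genes by the five filtering properties and build a supermatrix.

Computes occupancy, total tree length (substitution-rate proxy),
saturation, RCFV (compositional heterogeneity) and mean patristic distance
per gene, keeps the most complete genes, and concatenates them.
"""

from coalmorph import gene_properties as gp
from coalmorph import simdata
from coalmorph.io_formats import build_supermatrix

cfg = simdata.SimConfig(seed=5, n_taxa=10, n_genes=60, sites_per_gene=120)
data = simdata.simulate_dataset(cfg)
taxa = data.species_tree.leaf_labels()
trees = {a.name: t for a, t in zip(data.alignments, data.gene_trees)}

props = gp.compute_gene_properties(data.alignments, trees, taxa)
print("per-gene properties (head):")
print(props.head().round(4).to_string())

best = gp.rank_and_subset(
    [gp.GenePropertyRecord(g, *row) for g, row in props.iterrows()],
    "occupancy",
    K=20,
)
chosen = [a for a in data.alignments if a.name in set(best)]
sm, parts = build_supermatrix(chosen, taxa)
print(f"\nsupermatrix: {sm.n_taxa} taxa x {sm.length} columns, "
      f"{len(parts.blocks)} partitions")
print(f"proportion of variable sites: {gp.proportion_variable_sites(sm):.3f}")
print(
    "Higher-occupancy matrices keep more taxa per column; the variable-site "
    "proportion is the signal metric used to compare filtered matrices."
)
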