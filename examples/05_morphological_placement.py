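"""Weight-calibrated morphological placement of query species.

Simulates an Mk morphological matrix on a known tree, calibrates
implied-weighting character weights against the reference topology, and
places held-out species back, scoring per-family accuracy.
"""

from coalmorph import morphology as mo
from coalmorph import simdata
from coalmorph.mk_engine import MkModel

tree = simdata.simulate_species_tree(14, seed=21)
mat, _ = simdata.simulate_morph_matrix(
    tree, 100, states_per_char=2, rate_distribution=0.25, seed=22
)
# two "families": the clades under the root's children
fam = {}
for g, child in enumerate(tree.children()[tree.root]):
    for t in tree.clade_leafset(child):
        fam[t] = f"fam{g + 1}"

model = MkModel(k=2, gamma_categories=4, gamma_alpha=1.0,
                ascertainment="lewis_variable")
records = []
for taxon in tree.leaf_labels()[:6]:
    pruned = tree.drop_leaf(taxon)
    ref = mat.subset_taxa([t for t in mat.taxa if t != taxon])
    weights = mo.calibrate_weights(ref, pruned, concavity=3.0)
    res = mo.place_query(pruned, ref, weights, mat.row(taxon), model,
                         query_id=taxon, groups=fam)
    records.append((taxon, res.assigned_group, fam[taxon]))
    print(f"{taxon}: best edge {res.best_edge}, pendant "
          f"{res.pendant_length:.3f}, assigned {res.assigned_group} "
          f"(truth {fam[taxon]})")

print()
print(mo.summarize_placements(records, set(fam.values())).to_string())
print(
    "\nEach query is scored on every reference edge (weighted Mk+G4 "
    "likelihood with the Lewis correction); the table aggregates per-group "
    "accuracy the way placement studies report it."
)
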