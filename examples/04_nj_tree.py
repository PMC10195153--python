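"""Neighbor-Joining clustering of populations from their mutation profiles.

Euclidean distances on the binary presence-absence matrix; Saitou-Nei NJ
with deterministic tie-breaking; Newick output with intergenic-style region
names safely quoted.
"""

import contevo as ce

# strong planted modularity so clades are visible by eye
cfg = ce.SimConfig(
    founders_per_pathway=2, replicates_per_founder=3,
    n_control_replicates=0, module_hit_prob=0.9,
    mutations_per_pop_mean=12.0, extinctions={}, assay_replicates=0, seed=4,
)
dataset = ce.simulate_mutation_dataset(cfg)

pa = ce.presence_absence(dataset.mutation_table)
dm = ce.euclidean_distance(pa)
tree = ce.neighbor_joining(dm)
print(f"{len(tree.leaf_names())} populations; unrooted NJ tree:")
print(ce.to_newick(tree))
print("# populations sharing a pathway module cluster into the same clade")
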