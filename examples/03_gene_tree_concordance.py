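"""Gene-tree/species-tree concordance: RF distances and tree-space MDS.

Estimates NJ gene trees with bootstrap supports from simulated loci,
computes pairwise Robinson-Foulds distances to the true species tree, and
embeds tree space in 2-D with classical MDS. Trees close to the origin of
the embedding (where the species tree sits) agree with it topologically.
"""
import numpy as np

from tephrimark.simulate import SimConfig, simulate_dataset
from tephrimark.treekit import (
    avg_bootstrap,
    bootstrap_support,
    classical_mds,
    rf_matrix,
)

cfg = SimConfig(n_taxa=8, n_loci=10, tree_depth=0.05, dropout_prob=0.0,
                background_length=35_000, seed=3)
_, _, loci, truth = simulate_dataset(cfg)

gene_trees = [bootstrap_support(aln, 100, seed=i) for i, aln in enumerate(loci)]
ids = [a.locus_id for a in loci] + ["species"]
rfm = rf_matrix(gene_trees + [truth.true_tree], ids)
emb = classical_mds(rfm.rf.astype(float))

print("locus    RF-to-species  avg bootstrap   MDS1    MDS2")
for i, aln in enumerate(loci):
    print(f"{aln.locus_id}  {rfm.rf[i, -1]:13d} {avg_bootstrap(gene_trees[i]):14.1f}"
          f" {emb.coords[i, 0]:7.2f} {emb.coords[i, 1]:7.2f}")
print(f"species  {0:13d} {'-':>14} {emb.coords[-1, 0]:7.2f} {emb.coords[-1, 1]:7.2f}")
print(f"\nmean RF to species tree: {np.mean(rfm.rf[:-1, -1]):.2f} "
      f"(0 = identical topology; max {2 * (8 - 3)} for 8 taxa)")
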