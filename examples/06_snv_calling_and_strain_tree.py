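"""Four-strain SNV pipeline: reads -> alignment -> multi-sample calls ->
filters -> concatenated SNV pseudo-sequences -> TN93 distances -> NJ tree.

Two 'marijuana-like' and two 'hemp-like' strains are simulated from a planted
genealogy; the printed tree should place each pair together.  Requires
minimap2 on PATH.
"""

from cannaseq.pipelines import four_strain_tree, tree_separates_pairs

tree, dm = four_strain_tree(seed=1)
print("pairwise TN93 composite-likelihood distances over filtered SNV sites:")
print(dm.round(4).to_string())
print("\nneighbor-joining tree:")
print(tree)
print("\nmarijuana/hemp pairs separated:", tree_separates_pairs(tree))
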