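"""Gene-panel clustering against a random-panel ARI null.

Generates zero-inflated counts with a planted subtype-informative 150-gene
panel (standing in for ion-channel genes), clusters cells on the panel and
on 500 random panels of matched size, and ranks the focal panel's adjusted
Rand index within the null distribution.
"""

from hoinfo.clustering import identify_degs, preprocess
from hoinfo.recipes import gene_panel_ari_experiment
from hoinfo.synthetic import gen_counts

result = gene_panel_ari_experiment(seed=0, n_draws=500)
print(f"focal panel ARI      : {result.focal_ari:.3f}")
print(f"random-panel ARI mean: {result.null_mean:.3f}")
print(f"focal percentile     : {result.percentile:.1f}")
print(f"focal / null ratio   : {result.ratio:.1f}")
print()

# differential expression recovers the same panel from the labels
ds = gen_counts(300, 2000, n_subtypes=2, seed=0, panel_size=150)
em = preprocess(ds.data)
degs = identify_degs(em)
planted = set(ds.truth["panel_genes"])
hits = sum(g in planted for g in degs["gene"].head(150))
print(f"DEG analysis: {hits}/150 of the top-ranked genes are planted "
      f"panel members")
print()
print("The planted panel recovers the subtypes essentially perfectly while "
      "matched-size random panels hover near chance: a compact informative "
      "gene program, not panel size, carries the cell-type signal.")
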