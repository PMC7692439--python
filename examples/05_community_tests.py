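"""Do sampling sites structure the communities?  ANOSIM and one-way
PERMANOVA on Bray-Curtis distances, plus a non-metric MDS ordination.

ANOSIM R near 1 means between-site distances dominate within-site
distances; the PERMANOVA pseudo-F plays the same role on squared
distances.  Both p-values come from seeded label permutations.
"""
from otukit import SimulationConfig, anosim, generate_dataset, nmds, pairwise_dissimilarity, permanova_oneway, rarefy

table, metadata, _ = generate_dataset(SimulationConfig(seed=1))
table = rarefy(table, 7125, seed=1)
meta = metadata.for_table(table)

for compartment, samples in meta.groupby("compartment").groups.items():
    sub = table.select_samples(list(samples))
    d = pairwise_dissimilarity(sub, "bray_curtis")
    sites = meta.loc[list(samples), "site"]
    a = anosim(d, sites, n_permutations=999, seed=1)
    p = permanova_oneway(d, sites, n_permutations=999, seed=1)
    print(f"{compartment}: ANOSIM R={a.r:.2f} (p={a.p_value:.3f}), "
          f"PERMANOVA F={p.pseudo_f:.2f} (p={p.p_value:.3f}, "
          f"df={p.df_between},{p.df_within})")

embedding = nmds(pairwise_dissimilarity(table, "jaccard"), n_restarts=10, seed=1)
print(f"nMDS stress={embedding.stress:.3f} over {embedding.n_restarts} restarts")
print(embedding.coordinates.head(3).round(3))
# Stress < 0.2 is conventionally interpretable; coordinates feed a scatter
# plot colored by site/compartment.
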