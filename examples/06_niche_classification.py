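"""Levins niche breadth: which OTUs are generalists, which are abundant
habitat specialists, and how many OTUs the two compartments share.

B = 1 / sum_i P_ij^2 is the effective number of samples OTU j occupies
(P_ij = share of the OTU's reads in sample i).  B above 20 marks a
generalist, below 10 a specialist; abundant specialists (total reads
> 0.2% of the dataset) with > 20% mean relative abundance in one
plant x compartment group are habitat indicators.
"""
from otukit import (
    SimulationConfig,
    abundant_specialists,
    classify_niche,
    generate_dataset,
    generalist_otus,
    rarefy,
    shared_counts_frame,
    shared_otu_counts,
)

table, metadata, truth = generate_dataset(SimulationConfig(seed=1))
table = rarefy(table, 7125, seed=1)

classification = classify_niche(table)
print(classification["category"].value_counts().to_dict())
planted_gen = truth.otus_with_role("generalist")
hits = (classification.loc[list(planted_gen), "category"] == "generalist").mean()
print(f"planted generalists recovered: {hits:.0%}")

whole = generalist_otus(table, metadata, mode="whole")
print(f"whole-dataset generalists: {len(whole)}")

spec = abundant_specialists(table, metadata)
print(f"abundant specialists: {len(spec)}")
print(spec[["b_value", "total_reads"]].round(2).head(3))
first = spec.iloc[0]
print("top habitat of", spec.index[0], "->", first["preferred_habitats"][0])

venn = shared_counts_frame(shared_otu_counts(table, metadata, ("compartment",)))
print(venn)
# `shared` counts OTUs detected in both compartments - the candidate core
# community; `only_*` are compartment-exclusive OTUs.
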