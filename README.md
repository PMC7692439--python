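# otukit

Community analysis of 16S rRNA amplicon OTU count tables, built for
multi-habitat plant-microbiome surveys (rhizosphere vs. phyllosphere,
several sampling sites, replicate individuals). Starting from a finished
OTU × sample count matrix and a sample metadata table, `otukit` covers the
full downstream analysis:

* **Preprocessing** — global-singleton removal, taxonomy-based filtering
  (e.g. chloroplast 16S), shallow-sample exclusion, and seeded rarefaction
  without replacement to a common depth, optionally keeping below-depth
  samples.
* **Alpha diversity** — observed richness, bias-corrected Chao1, Simpson
  (1 − D), Pielou equitability, coverage ratio, and exact analytic
  rarefaction curves.
* **Beta diversity** — Bray-Curtis / Jaccard / Sørensen matrices, and the
  multiple-site partition of total Sørensen dissimilarity into species
  turnover and nestedness: bSOR = bSIM + bNES.
* **Group-structure tests** — ANOSIM and one-way PERMANOVA with seeded
  permutation p-values, and 2-D non-metric MDS (Kruskal stress-1).
* **Niche-breadth classification** — Levins' index per OTU,

      B_j = 1 / Σ_i P_ij²,  P_ij = proportion of OTU j's reads in sample i,

  the effective number of samples an OTU occupies: B = 1 for an OTU
  confined to one sample, B = N for a perfectly even OTU. OTUs with
  B > 20 are generalists, B < 10 specialists; abundant OTUs (> 0.2% of
  all reads) that are specialists and hold > 20% mean relative abundance
  in one plant × compartment group are *abundant habitat specialists*.
  Shared-OTU (Venn) counts between compartments complete the picture.
* **Synthetic surveys** — a seeded generator that plants generalist,
  specialist and background OTUs with known labels, so every stage can be
  validated against ground truth.

See `docs/methods.md` for the formulas, estimator variants and design
choices, and `examples/` for one short runnable script per capability.

## Worked example

Simulate a 76-sample, three-site survey, rarefy it, test site structure
and classify niche breadth (this is `examples/05_community_tests.py` and
`examples/06_niche_classification.py` condensed):

```python
from otukit import (SimulationConfig, generate_dataset, rarefy,
                    pairwise_dissimilarity, anosim, permanova_oneway,
                    classify_niche, abundant_specialists)

table, metadata, truth = generate_dataset(SimulationConfig(seed=1))
table = rarefy(table, 7125, seed=1)
meta = metadata.for_table(table)

for compartment, samples in meta.groupby("compartment").groups.items():
    sub = table.select_samples(list(samples))
    d = pairwise_dissimilarity(sub, "bray_curtis")
    a = anosim(d, meta.loc[list(samples), "site"], n_permutations=999, seed=1)
    p = permanova_oneway(d, meta.loc[list(samples), "site"], n_permutations=999, seed=1)
    print(f"{compartment}: ANOSIM R={a.r:.2f} (p={a.p_value:.3f}), "
          f"PERMANOVA F={p.pseudo_f:.2f} (p={p.p_value:.3f})")

cats = classify_niche(table)["category"]
print(cats.value_counts().to_dict())
print("abundant specialists:", len(abundant_specialists(table, metadata)))
```

prints

```
phyllosphere: ANOSIM R=0.98 (p=0.001), PERMANOVA F=19.35 (p=0.001)
rhizosphere: ANOSIM R=1.00 (p=0.001), PERMANOVA F=19.20 (p=0.001)
{'generalist': 595, 'specialist': 203, 'intermediate': 196}
abundant specialists: 14
```

R near 1 and p = 0.001 (the floor at 999 permutations) say that samples
from the same site are far more similar than samples from different
sites, in both compartments. The classifier recovers all 14 planted
specialists as abundant habitat specialists; the planted generalists land
in the generalist class (mean B ≈ 71 of a possible 76), alongside background
OTUs that are genuinely spread across many samples.

## Command line

The same pipeline is scriptable from a shell:

```bash
otukit simulate --out data/ --seed 1
otukit run --table data/otu_table.tsv --metadata data/metadata.tsv \
           --out results/ --seed 1
```

`run` writes every stage's TSV/JSON (alpha table, distance matrices, beta
partition, test results, nMDS coordinates, niche classification, shared
OTU counts) plus a `manifest.json` with versions, seeds and thresholds;
rerunning with the same manifest settings reproduces every file bit for
bit. Individual stages are available as `filter`, `rarefy`, `alpha`,
`beta`, `test` and `niche` subcommands.

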