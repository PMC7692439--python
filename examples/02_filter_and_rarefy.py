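"""Standard OTU-table preprocessing: singleton removal, shallow-sample
exclusion, and seeded rarefaction to a common depth.

Samples at or above the target depth are subsampled without replacement to
exactly that depth; shallower samples are kept unchanged so no habitat is
lost from the analysis.
"""
from otukit import (
    SimulationConfig,
    drop_shallow_samples,
    filter_global_singletons,
    generate_dataset,
    rarefy,
)

table, metadata, _ = generate_dataset(SimulationConfig(seed=1))
print("raw:", table)

table = filter_global_singletons(table)     # dataset-wide single reads are noise
table = drop_shallow_samples(table, 1000)   # failed sequencing runs
print("filtered:", table)

rarefied = rarefy(table, depth=7125, seed=1, keep_below_depth=True)
depths = rarefied.sample_depths
print("rarefied:", rarefied)
print(f"samples at exactly 7125 reads: {(depths == 7125).sum()}, "
      f"kept below depth: {(depths < 7125).sum()}")
# Equalized depths make richness and niche-breadth values comparable across samples.
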