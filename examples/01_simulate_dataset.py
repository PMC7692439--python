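"""Simulate a multi-site rhizosphere/phyllosphere OTU survey with planted guilds.

The generator mirrors a three-site field design (one plant with 8 replicate
individuals at site 1, three plants with 5 replicates at sites 2-3, two
compartments each) and plants three OTU guilds: ubiquitous generalists,
habitat-restricted specialists, and a heavy-tailed background community.
"""
from otukit import SimulationConfig, generate_dataset

table, metadata, truth = generate_dataset(SimulationConfig(seed=1))

print(table)
print(metadata.frame.groupby(["site", "compartment"]).size().unstack())
print("planted roles:", {role: len(truth.otus_with_role(role))
                         for role in ("generalist", "specialist", "background")})
print("one specialist's preferred habitat:",
      next(iter(truth.preferred_group.items())))
# Sample depths are uneven on purpose: some fall below the usual 7125-read
# rarefaction depth, as happens in real sequencing runs.
print("depth range:", int(table.sample_depths.min()), "-", int(table.sample_depths.max()))
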