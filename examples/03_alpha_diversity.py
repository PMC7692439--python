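"""Per-sample alpha diversity: observed and Chao1 richness, Simpson (1-D),
Pielou equitability, and the analytic rarefaction curve.

The coverage ratio S_obs / S_Chao1 estimates how completely sequencing
sampled each community (1 = every estimated OTU observed).
"""
from otukit import SimulationConfig, alpha_table, generate_dataset, group_summary, rarefaction_curve, rarefy

table, metadata, _ = generate_dataset(SimulationConfig(seed=1))
table = rarefy(table, 7125, seed=1)

alpha = alpha_table(table)
print(alpha.head(4).round(3))
print("coverage ratio range:",
      alpha["coverage_ratio"].min().round(3), "-", alpha["coverage_ratio"].max().round(3))

summary = group_summary(alpha, metadata, factors=("plant", "compartment"))
print(summary[["n_samples", "s_obs_mean", "s_obs_sd"]].round(1).head())

# Expected richness when drawing q reads from the first sample, no simulation needed.
sample = table.sample_ids[0]
curve = rarefaction_curve(table.counts[sample], [100, 1000, 5000])
print(f"expected OTUs in {sample} at 100/1000/5000 reads:", curve.round(1))
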