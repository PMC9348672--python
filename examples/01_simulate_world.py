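"""Generate the synthetic world and look at the simulated collection.

Builds Brazil-like monthly climate, precipitation-isotope and static
grids, draws a museum-like feather sample set from the known transfer
model, and prints its descriptive statistics.
"""

from plumascape import SimConfig, descriptive_stats, simulate_samples, simulate_surfaces

cfg = SimConfig(seed=42, n_sites=192, n_locations=129, clustered=True)
stack = simulate_surfaces(cfg)
samples, truth = simulate_samples(stack, cfg)

print(f"grid layers generated: {len(stack)}")
stats = descriptive_stats(samples)
for key, val in stats.items():
    print(f"  {key}: {val:.1f}" if isinstance(val, float) else f"  {key}: {val}")
print(f"generating coefficients: {truth.coef}")
print(f"true isotope window: {truth.window}")
# d2h_min/max are the extreme feather values (permil VSMOW) the transfer
# model plus noise produced; n_unique_locations mimics museum hotspots.
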