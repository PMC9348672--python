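"""Compute the 19 BIOCLIM variables from a monthly climatology.

Averages the simulated monthly grids over the year range, derives
bio1..bio19 and prints the values at one location (annual mean
temperature, annual precipitation, temperature range, and the
quarter-based precipitation aggregates that drive the isoscape model).
"""

from plumascape import SimConfig, compute_biovars, simulate_surfaces
from plumascape.synthetic import climatology_from_stack

cfg = SimConfig(seed=7)
stack = simulate_surfaces(cfg)
clim = climatology_from_stack(stack, cfg)
bio = compute_biovars(clim)

lon, lat = -47.9, -15.8  # central Brazil
for name, label, unit in [
    ("bio1", "annual mean temperature", "degC"),
    ("bio7", "annual temperature range", "degC"),
    ("bio12", "annual precipitation", "mm"),
    ("bio18", "precipitation of warmest quarter", "mm"),
]:
    print(f"{name} {label}: {bio[name].value_at(lon, lat):.1f} {unit}")
# bio18 always lies between bio17 (driest quarter) and bio16 (wettest):
print(f"bio17 <= bio18 <= bio16: "
      f"{bio['bio17'].value_at(lon, lat):.0f} / "
      f"{bio['bio18'].value_at(lon, lat):.0f} / "
      f"{bio['bio16'].value_at(lon, lat):.0f} mm")
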