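"""From a label mask to calibrated droplet measurements and strata.

Renders a synthetic segmentation mask for one fish, measures every
droplet (centroid, area, Feret diameter in µm), and bins droplets into
200 µm anterior-posterior strata anchored at the most anterior droplet.
"""

import numpy as np

import ldmorph as lm
from ldmorph.simulate import simulate_fish

rng = np.random.default_rng(0)
cfg = lm.SimulationConfig(lipid_fraction=0.2, sl_range=(7.0, 8.0))
fish, droplets = simulate_fish(cfg, "control", rng, with_droplets=True)

mask, truth = lm.render_masks(droplets, pixel_size=2.0, seed=0)
print(f"rendered {len(truth)} droplets on a {mask.pixels.shape} mask "
      f"(pixel size {mask.pixel_size} um)")

table, report = lm.measure_droplets(mask)
print(f"measured {report['n_measured']} droplets "
      f"({report['n_discarded_below_min_area']} below the "
      f"{report['min_area_px']}-px minimum)")

table["stratum"] = lm.assign_strata(table)
summary = lm.stratum_summaries(table)
print("\nper-stratum droplet count and mean Feret diameter (um):")
print(summary.to_string(index=False))
print("\nStratum 1 is the anterior (oldest) end of the depot. Mean Feret "
      "diameter is the adipocyte-size proxy; with ~50 droplets per fish "
      "the mild posterior size deficit is visible only on average, not "
      "in every stratum.")
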