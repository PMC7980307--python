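"""Suitability thresholding and range-change accounting.

Thresholds the synthetic suitability raster with the max-sensitivity-plus-
specificity rule, derives binary maps for a cooler (larger range) and a
warmer (smaller range) climate slice, and prints the range-change table:
suitable cells, per cent of the study area, and per cent change relative to
the present map.
"""

import numpy as np

from skyisland.range_dynamics import binarize, max_sss_threshold, range_report
from skyisland.synthetic import WorldConfig, make_world

world = make_world(WorldConfig(), seed=11)
suit = world.rasters["suitability"]

rng = np.random.default_rng(0)
presence = np.clip(
    [suit.values[r, c] for r, c in world.nodes.values()], 0, 1
)
background = rng.choice(suit.values.ravel(), size=300, replace=False)
thr = max_sss_threshold(presence, np.clip(background, 0, 1))
print(f"max-SSS threshold: {thr:.3f}")

slices = {
    "present": suit,
    "cooler_past": suit.like(np.clip(suit.values * 1.6, 0, 1)),
    "warmer_future": suit.like(np.clip(suit.values * 0.5, 0, 1)),
}
maps = {k: binarize(v, thr) for k, v in slices.items()}
report = range_report(maps, present="present")
print("\nRange report (positive change = larger suitable range than today):")
print(report.to_string())
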