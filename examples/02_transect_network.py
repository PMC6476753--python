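"""Straight-line transects on the 1-km grid.

Shows the distance conventions (same cell 0 km, any 8-neighbour 1 km),
the supercover cell traversal including the exact-corner rule, and the
elevation / land-use summaries one pair's transect carries.
"""

import numpy as np

from landres import (LandscapeRaster, build_network, euclidean_km,
                     supercover_cells)
from landres.rasters import LANDUSE_CLASSES

print("grid distance conventions:")
print(f"  same cell      (5,5)-(5,5): {euclidean_km((5, 5), (5, 5))} km")
print(f"  8-neighbour    (5,5)-(6,6): {euclidean_km((5, 5), (6, 6))} km")
print(f"  3-4-5 triangle (0,0)-(3,4): {euclidean_km((0, 0), (3, 4))} km")

print("\nsupercover of the 45-degree segment (0,0)->(2,2) — exact corner")
print("crossings include both adjacent cells:")
print(f"  {supercover_cells((0, 0), (2, 2))}")

rng = np.random.default_rng(5)
elevation = LandscapeRaster(values=rng.uniform(200, 800, (12, 12)),
                            kind="elevation")
landuse = LandscapeRaster(values=rng.choice([1, 1, 1, 2, 3], (12, 12)),
                          kind="landuse")
network = build_network({"bear_a": (1, 1), "bear_b": (10, 8)},
                        elevation, landuse)
profile = network.profile("bear_a", "bear_b")

print(f"\ntransect bear_a -> bear_b: {profile.euclid_km:.2f} km, "
      f"{len(profile.cells)} cells")
print(f"  elevation mean {profile.elev_mean:.0f} m, "
      f"max difference {profile.elev_maxdiff:.0f} m, "
      f"SD {profile.elev_sd:.0f} m, CV {profile.elev_cv:.3f}")
print("  land-use cells on the transect:")
for code, n in profile.landuse_counts.items():
    if n:
        print(f"    {LANDUSE_CLASSES[code]:<12} {n}")
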