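"""Bulk-normalized probe density map with a planted interaction hotspot.

Generates a 500-frame trajectory of isopropanol pseudo-atoms in a 40 Å box —
uniform bulk plus one Gaussian blob enriched 20x over bulk — builds the
density grid, and extracts hotspots at the conventional isovalue of 12.
"""

import numpy as np

from allosite.cosolvent import bulk_number_density, compute_density_grid, extract_hotspots
from allosite.structio import write_grid
from allosite.synthetic import HotspotSpec, ProbeTrajectoryConfig, gen_probe_trajectory

spot = HotspotSpec(center=(20.0, 20.0, 20.0), sigma=2.0, enrichment=20.0)
cfg = ProbeTrajectoryConfig(seed=1, box=(40.0, 40.0, 40.0), n_probes=200,
                            n_frames=500, hotspots=(spot,))
frames, truth = gen_probe_trajectory(cfg)

grid = compute_density_grid(frames, "IPA", origin=(0, 0, 0), dims=(40, 40, 40),
                            spacing=1.0, bulk_density=truth["bulk_density"])
hotspots = extract_hotspots(grid, isovalue=12.0, min_voxels=4)

print(f"grid mean density  : {grid.values.mean():.3f}  (1.0 = bulk)")
print(f"hotspots at iso 12 : {len(hotspots)}")
for h in hotspots:
    err = np.linalg.norm(h.centroid - np.array(spot.center))
    print(f"  centroid {np.round(h.centroid, 2)}  volume {h.volume:.0f} A^3  "
          f"peak {h.peak:.1f}x bulk  (centroid error {err:.2f} A)")

write_grid(grid, "scratch_map.dx")  # viewable in PyMol; CNS dialect also available
# The single recovered hotspot sits at the planted center; everywhere else the
# density normalizes to ~1.0, i.e. indistinguishable from bulk solvent.
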