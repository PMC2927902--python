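"""Segment a synthetic airspace volume and histogram its distance map.

A synthetic branching cavity stands in for an airway tree: region growing
from a seed extracts the connected cavity, small disconnected particles are
removed, and the Euclidean distance transform histogram summarizes the
airspace dimensions - the same pipeline applied to reconstructed lung
volumes, where distance histograms compare protocols.
"""

import numpy as np

import widefieldct as w

# synthetic volume: a wide duct with a side branch, plus floating specks
rng = np.random.default_rng(0)
vol = np.zeros((48, 48, 48))
vol[8:40, 20:28, 20:28] = 1.0          # main duct
vol[20:28, 24:44, 22:26] = 1.0         # side branch
for _ in range(30):                     # disconnected specks
    z, y, x = rng.integers(2, 46, 3)
    if vol[z, y, x] == 0:
        vol[z, y, x] = 1.0
vol += rng.normal(0, 0.05, vol.shape)   # gray-value noise

seed = (12, 24, 24)
region = w.region_grow(vol, seed, (0.5, 1.5))
print(f"region grown from seed {seed}: {int(region.mask.sum())} voxels")

clean = w.remove_small_components(region.mask, min_voxels=10)
print(f"after removing particles < 10 voxels: {int(clean.sum())} voxels")

dist = w.euclidean_distance_transform(clean, voxel_size_um=1.48)
hist = w.distance_histogram(dist, bin_width_um=1.0)
print(f"max lumen half-width: {dist.max():.1f} um")
print("\ndistance histogram (um -> voxels):")
for lo, hi, c in zip(hist.bin_edges_um[:-1], hist.bin_edges_um[1:], hist.counts):
    if c:
        print(f"  [{lo:4.1f}, {hi:4.1f})  {int(c):>6}  {'#' * int(np.log2(c + 1))}")
print("\nThe histogram tail reflects the widest airways; protocol-induced "
      "artifacts would show up as counts shifting between adjacent bins.")
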