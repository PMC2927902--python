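"""Merge three subscans into wide projections and reconstruct the slice.

The central subscan carries half the projections of the lateral ones, so
the merge stage first doubles it by angular interpolation, then registers
each seam by the mean-squared-difference cutline search, stitches, builds
the sinogram and reconstructs by ramp-filtered backprojection.  The result
is compared against reconstructing an ideal wide detector directly.
"""

import numpy as np

import widefieldct as w

geom = w.plan_widefield(384, 144, 24)
phantom = w.shepp_logan(384)
P = 96
angles = np.arange(P) * (180.0 / P)
half_angles = np.arange(P // 2) * (180.0 / (P // 2))

subs = [
    w.forward_project(phantom, half_angles if off == 0 else angles, off, 144)
    for off in geom.offsets_px
]
print("subscan projection counts:", [s.n_projections for s in subs])

merged = w.merge_subscans(subs, geom, search_radius_px=3)
print(f"merged: {merged.projections.shape[0]} projections of "
      f"{merged.merged_width_px} px, seams at columns {merged.cutlines_px}")

stack = w.build_sinograms(merged)
rec = w.reconstruct_slice(stack.sinograms[0], merged.angles_deg).image

wide = w.wide_projection(phantom, angles)
rec_ideal = w.reconstruct_slice(wide, angles).image
rmse = np.sqrt(np.mean((rec - rec_ideal) ** 2)) / np.ptp(rec_ideal)
print(f"\nRMSE vs ideal wide-detector reconstruction: {100*rmse:.2f}% of range")
print("Sub-1% means the stitched, half-sampled acquisition loses almost "
      "nothing relative to a detector three times as wide.")
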