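"""Plan a three-subscan wide-field scan and its dose-reduction ladder.

A 1024-px detector with 100-px overlaps covers a 2872-px-wide slice.  The
gold standard fulfils the sampling theorem (P = D*pi/2 per subscan) and
needs 13534 projections; the ladder scales the subscan counts down in
multiples of 874, the central subscan optionally carrying half the lateral
count.  "Dose" is the projection total relative to the gold standard.
"""

import widefieldct as w

geom = w.plan_widefield(2872, 1024, 100, pixel_size_um=1.48)
ref = w.reference_total(geom)
print(
    f"{geom.n_subscans} subscans of {geom.detector_width_px} px, "
    f"covered width {geom.covered_width_px} px = {geom.covered_fov_mm} mm"
)
print(f"gold standard total: {ref} projections")

steps = [(6, 6, 6), (5, 5, 5), (4, 4, 4), (3, 3, 3), (2, 2, 2), (1, 0.5, 1)]
ladder = w.make_protocol_ladder(geom, 874, steps)
print("\nlabel  s1    s2    s3    total  dose%  saving%")
for p in ladder:
    s1, s2, s3 = p.per_subscan_projections
    saving = w.dose_reduction_pct(p, ref)
    print(
        f"{p.label:>5} {s1:>5} {s2:>5} {s3:>5} {p.total_projections:>6} "
        f"{p.dose_fraction_pct:>6} {saving:>8}"
    )
print(
    "\nThe last rung acquires", ladder[-1].total_projections,
    "projections - an", w.dose_reduction_pct(ladder[-1], ref),
    "% saving in acquisition time and radiation dose.",
)
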