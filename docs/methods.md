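# Methods

## Scan model and coordinate conventions

The toolkit models a parallel-beam tomographic microscope.  A *subscan* is
one 180° rotation acquired with the sample displaced laterally by
`offset_px` relative to the rotation axis; the detector of width `D` pixels
then samples rays at signed detector coordinates
`s ∈ [offset − D/2, offset + D/2)`, with `s = 0` on the axis.  An odd number
of subscans — one central plus symmetric pairs of half ring-scans spaced by
`D − overlap` — covers a merged width of `n·D − Σ overlaps` pixels.

Conventions used consistently by the simulator, the merge stage and the
reconstructor:

* the rotation axis passes through pixel index `w//2` of any image or
  profile (this is the rotation center of the underlying projection and
  backprojection routines; for even widths the geometric center falls half
  a pixel off this index, which is why tests of exact mirror identities use
  odd widths);
* angles are degrees; at θ = 0 the detector coordinate equals the image
  x-coordinate, at θ = 90° the upward y-coordinate;
* projection rows are line integrals in attenuation × pixel-size units; the
  profile at θ + 180° is the axis-mirrored profile at θ
  (`mirror_profile`, a flip plus a one-pixel roll for even widths).

## Sampling arithmetic and protocol ladders

A reconstruction of width `D` pixels needs `P = D·π/2` equiangular
projections over 180°.  `P` is kept as a real number throughout and only
final totals are rounded (half away from zero); this convention
simultaneously reproduces the reference counts 4825 (`3072·π/2`), 14476
(`9·1024·π/2`) and 13534 (`3·(3·1024 − 200)·π/2`) for the three-subscan,
100-px-overlap geometry, which per-term rounding does not.

The gold-standard protocol acquires the full covered-width requirement in
every subscan: `reference_total = round(n · covered_width · π/2)`.  Ladders
of dose-reduced protocols assign each subscan a multiple (integer or
half-integer) of a base unit; the central subscan must carry the lateral
count or half of it, so merging needs at most a factor-of-two angular
interpolation.  Half-count rungs are derived by halving the *rounded*
lateral count, which keeps the pair exactly mergeable; an even base unit
avoids the non-integral halves that an odd lateral count would produce.
The dose of a protocol is its projection total as a percentage of the
reference total — no physical dose calculation is attempted, since
acquisition time and imparted dose both scale linearly with the projection
count at fixed exposure.

The shipped `TABLE1` constant records the printed 19-protocol study ladder
verbatim; a few of its rows are internally inconsistent with exact
multiples of the 874-projection base unit by ±1 projection (e.g. 2186 vs
2185, 3934 vs 3933).  The generator follows exact nearest-integer
arithmetic and reproduces every printed dose percentage.

## Phantom simulator

`shepp_logan` evaluates the canonical 10-ellipse head phantom (additive
gray levels; outer shell 2.0, brain 1.02, low-contrast interior features)
at any width; a pixel's value is the sum of the ellipses containing the
pixel center.  `disc_phantom` builds uniform discs with area-fraction
(supersampled) edges so line integrals approach the analytic chord length.
Forward projection computes full-width line-integral profiles (bilinear
rotation sampling at one-pixel ray spacing) and extracts the subscan's
lateral band, so the union of the subscan bands at one angle is *exactly*
the wide-detector projection of the same phantom — which makes merged-vs-
wide comparisons sharp tests of the merge stage rather than of
interpolation noise.

Projections are emitted in the absorption domain by default.  A
transmittance mode (`I = flat·exp(−μ·scale) + dark`) generates realistic
detector counts plus Gaussian flat/dark frames, giving the normalization
stage honest inputs; the attenuation scale keeps the exponent in a
numerically sane range.  All randomness (frame noise, phantom noise) is
seeded.

## Merging

Pipeline order: normalize each subscan (`(I − Ī_D)/(Ī_F − Ī_D)`, clipped to
`[0, 2]`, dead columns are an error naming them) → interpolate half-count
subscans up to the merged projection count (linear in angle, pixel-wise,
in the absorption domain; the wrap past the last angle uses the mirrored
first projection) → register each seam and pick its cutline → stitch →
rearrange into per-slice sinograms.

Cutline detection follows a mean-squared-difference criterion: over lateral
displacements within a search radius, the shift minimizing the MSD of the
overlapping bands is chosen; the cut column is the per-column MSD minimum
at that shift, ties broken toward the overlap center.  A degenerate overlap
— statistically flat, or an MSD landscape whose minimum is not well below
its median (uncorrelated content sits near `2σ²` at every shift) — yields a
warning and the nominal overlap with a center cut.  The cut column belongs
to the left subscan, fixing the merged width at `Σ widths − Σ overlaps`
(the published merged width of 2792 px for 3×1024 with overlaps 141/138 is
one pixel narrower than this arithmetic; the convention here is fixed as
stated).  Stitching is a hard cut; an optional feather width cross-fades
the seam and defaults to 0.  Registration is performed once per seam on the
angle-averaged strips — the stage positions do not move during a scan, so
per-angle registration would only track noise.

The 360° off-center mode folds a full rotation into half as many wide
projections: the θ + 180° projection is flipped and stitched to the θ
projection about the axis column, covering up to twice the detector width.

Sinogram assembly is pure re-indexing (sinogram *n* is row *n* of every
merged projection in angle order) and round-trips bit-exactly.

## Reconstruction

Slices are reconstructed by filtered backprojection on the merged width:
ramp (Ram-Lak) filter by default, Shepp–Logan and Hann apodizations
optionally, sinogram rows zero-padded to a power of two before filtering,
values outside the inscribed circle set to zero.  The FFT-regridding
algorithm used on real beamline clusters is treated as an equivalence
class: FBP satisfies the same contracts (linearity, locality, undersampling
streaks) without bit-exact agreement.  Float images are produced
internally; an 8-bit min–max-windowed export is available.

## Quality assessment

For measured volumes, protocol quality versus a gold standard is the
binarized slice difference: both slices of a sampled pair are Otsu-
thresholded independently (256 histogram bins; per-slice thresholds, since
a global threshold is not stated for the published workflow) and
`E = Σ |Slice_i − Slice_B|` counts disagreeing pixels — an L1 metric.
Slices are sampled at indices `0, stride, 2·stride, …`; stride 5 on a
1024-slice volume evaluates 205 slices, the only convention reproducing
that printed count.  Mean errors across a ladder are normalized onto the
ladder's dose scale by an affine map sending the largest error to the low
end (the exact normalization behind the published 16–116% quality scale is
under-specified; the endpoint mapping is this package's declared choice).

The *simulated* curve (`simulate_quality_curve`) scores each protocol's
end-to-end reconstruction of a noisy Shepp–Logan reference by the sum of
the absolute difference image against that reference.  The binarized count
is available (`metric="binary"`) but saturates on this phantom: a global
Otsu threshold falls in the wide empty gap between background (0) and
brain (≈1), so neither moderate noise nor undersampling streaks flip
pixels, and the binary count stays flat across protocols.  The absolute
difference responds continuously to streak energy and decreases strictly
with the projection total.

Study conditions for the desk-scale replication (chosen once): 384-px
phantom, three 144-px subscans with 24-px overlaps, five-protocol ladder on
base unit 120 (multiples 5, 4, 3, 2 and 1/½, spanning 99% down to 17%
dose), additive Gaussian noise of sd 0.02 on the unit-scale phantom (the
reference noise level is not published; 2% of the brain gray level is a
plausible detector noise floor).  What the phantom run does *not* model:
beamline photon statistics, scintillator/optics blur, ring artifacts,
sample drift — so quantitative quality percentages are not comparable to
measured-tissue values, only the trend and ranking are.

Ordinary least squares (`fit_line`) provides the slope/intercept/R² of
quality-vs-dose trends.  The published regression coefficients are
beamline-data-dependent and are not reproduced numerically.

## Morphometry

Airway-style segmentation uses threshold-interval region growing: the
connected component (26-connectivity by default, 6 optionally) of
in-interval voxels containing a user-placed seed.  Keeping seed coordinates
fixed across protocol volumes makes segmentations comparable; growing is
idempotent from any voxel of a returned mask.  Small disconnected particles
are removed by connected-component size filtering (the published cleanup
does not state its size threshold; it is a parameter, default 1 = keep
all).  The Euclidean distance transform maps each foreground voxel to its
distance (µm) to the nearest background voxel; its histogram (1 µm bins by
default) summarizes airspace dimensions, with counts conserving the
foreground census.

## Numerical choices and degenerate inputs

* Rounding: half away from zero for all protocol arithmetic.
* Projector/reconstructor tolerances: band extraction is exact; merged
  projections match wide-detector projections to machine precision away
  from cutlines for noiseless input; FBP of a supersampled disc at the
  sampling-theorem count recovers the interior mean to ≲0.1%.
* Degenerate inputs raise: constant images (Otsu), all-foreground masks
  (EDT), single-angle sinograms, NaNs, dead detector columns, seeds outside
  their interval, overlaps ≥ detector width, odd 360° projection counts.
* Determinism: identical configs and seeds produce bit-identical stage
  outputs (verified by manifest digests in the workbench).

## Problem sizes

Tests and the acceptance script run phantom studies at 384 px (merge,
quality ladder), 256 px (FBP disc), 128 px and below (unit tests), with
≤16³ morphology fixtures — sizes at which every check completes in seconds
to a few minutes on one CPU while exercising the same code paths as
full-scale runs.
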