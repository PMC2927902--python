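"""Merging laterally offset subscan projections into wide-field projections.

The stages run in acquisition-pipeline order: flat/dark normalization of
every subscan, angular interpolation of subscans acquired with fewer
projections, mean-squared-difference cutline detection in each overlap, hard
stitching at the cutlines, and re-indexing of the merged projections into
per-slice sinograms.  A 360-degree off-center acquisition ("flip and
stitch") is supported as the two-subscan special case where the second half
rotation plays the role of the second lateral position.

Conventions fixed here (and relied on by the recon stage):

* the cut column belongs to the left subscan, so the merged width is exactly
  ``sum(widths) - sum(overlaps)``;
* interpolation is linear in angle, pixel-wise, in the absorption domain;
* stitching is a hard cut (no feathering) unless a feather width is given.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .phantom_sim import SubscanSet, mirror_profile
from .protocols import ScanGeometry

__all__ = [
    "WideProjectionSet",
    "SinogramStack",
    "normalize",
    "flip_stitch_360",
    "interpolate_missing",
    "find_cutline",
    "stitch",
    "merge_subscans",
    "build_sinograms",
    "sinograms_to_projections",
]


@dataclass
class WideProjectionSet:
    """Merged wide projections plus seam bookkeeping.

    ``provenance[j]`` is the index of the subscan every column j was copied
    from; ``cutlines_px`` records, per seam, the merged-frame column of the
    last pixel taken from the left subscan.
    """

    projections: np.ndarray  # [P, merged_width] or [P, rows, merged_width]
    angles_deg: np.ndarray
    cutlines_px: tuple[int, ...] = ()
    provenance: np.ndarray | None = None
    axis_col_px: int | None = None  # rotation-axis column in the merged frame

    def __post_init__(self) -> None:
        self.projections = np.asarray(self.projections, dtype=float)
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        if self.projections.shape[0] != self.angles_deg.shape[0]:
            raise ValueError("one merged projection per angle required")

    @property
    def merged_width_px(self) -> int:
        return int(self.projections.shape[-1])


@dataclass
class SinogramStack:
    """Per-slice sinograms: ``sinograms[n]`` is row n of every projection."""

    sinograms: np.ndarray  # [n_rows, P, merged_width]

    def __post_init__(self) -> None:
        self.sinograms = np.asarray(self.sinograms, dtype=float)
        if self.sinograms.ndim != 3:
            raise ValueError("sinogram stack must be 3-D [rows, angles, width]")


def normalize(
    projection: np.ndarray,
    darks: np.ndarray,
    flats: np.ndarray,
    clip_max: float = 2.0,
    eps: float = 1e-9,
) -> np.ndarray:
    """Flat/dark-field correction ``(I - <I_D>) / (<I_F> - <I_D>)``.

    Dark and flat stacks are averaged over their first axis; a blank-beam
    projection maps to 1.  Columns where the averaged flat does not exceed
    the averaged dark (dead pixels) raise an error naming them.
    """
    projection = np.asarray(projection, dtype=float)
    dark = np.mean(np.asarray(darks, dtype=float), axis=0)
    flat = np.mean(np.asarray(flats, dtype=float), axis=0)
    denom = flat - dark
    dead = np.nonzero(~(denom > eps))
    if dead[0].size:
        cols = np.unique(dead[-1])
        raise ValueError(f"dead detector columns (flat <= dark): {cols.tolist()}")
    out = (projection - dark) / denom
    return np.clip(out, 0.0, clip_max)


def interpolate_missing(subscan: SubscanSet, target_count: int) -> SubscanSet:
    """Raise a subscan's angular sampling to ``target_count`` projections.

    The acquired rows are kept exactly at their angles; every inserted row is
    the pixel-wise linear interpolation of its two angular neighbours at the
    appropriate angular fraction.  Past the last acquired angle the 180-degree
    periodicity of parallel-beam data is used: the profile at ``theta + 180``
    is the mirrored profile at ``theta``.  ``target_count`` must be an
    integer multiple of the acquired count (protocols guarantee the ratio is
    a power of two, in practice 1 or 2).
    """
    P = subscan.n_projections
    if target_count % P:
        raise ValueError(
            f"target count {target_count} is not a multiple of the acquired "
            f"count {P}"
        )
    r = target_count // P
    if r == 1:
        return subscan
    step = (subscan.angles_deg[1] - subscan.angles_deg[0]) if P > 1 else 180.0
    proj = subscan.projections
    # neighbour past the end: first projection advanced by the angular span,
    # mirrored if that span is the 180-degree wrap
    span = step * P
    wrap = proj[0]
    if np.isclose(span % 360.0, 180.0):
        wrap = mirror_profile(wrap)
    ext = np.concatenate([proj, wrap[np.newaxis]], axis=0)
    out_shape = (target_count,) + proj.shape[1:]
    out = np.empty(out_shape)
    for k in range(target_count):
        i, frac = divmod(k, r)
        t = frac / r
        out[k] = ext[i] if t == 0 else (1.0 - t) * ext[i] + t * ext[i + 1]
    angles = subscan.angles_deg[0] + np.arange(target_count) * (step / r)
    return SubscanSet(
        projections=out,
        angles_deg=angles,
        offset_px=subscan.offset_px,
        darks=subscan.darks,
        flats=subscan.flats,
    )


def find_cutline(
    left_strip: np.ndarray,
    right_strip: np.ndarray,
    nominal_overlap_px: int,
    search_radius_px: int = 0,
    min_overlap_px: int = 8,
    var_eps: float = 1e-12,
) -> tuple[int, int]:
    """Register two overlapping strips and pick the seam column.

    The right strip nominally overlaps the last ``nominal_overlap_px``
    columns of the left strip.  For every candidate lateral displacement
    ``d`` in ``[-search_radius, +search_radius]`` of the right strip, the
    mean-squared difference between the overlapping bands is evaluated; the
    returned ``shift_px`` is the displacement correction (``-d`` for a strip
    physically displaced by ``+d``).  ``cut_col`` is the column (indexed
    within the corrected overlap, 0-based from its left edge) with the
    smallest per-column mean-squared difference, ties broken toward the
    overlap center.

    A statistically flat overlap (zero variance in both bands) cannot be
    registered; a warning is issued and the nominal overlap with a center
    cut is returned.
    """
    left = np.atleast_2d(np.asarray(left_strip, dtype=float))
    right = np.atleast_2d(np.asarray(right_strip, dtype=float))
    ov0 = int(nominal_overlap_px)
    if ov0 < 1:
        raise ValueError("nominal overlap must be at least 1 px")

    best = None
    all_msd = []
    for d in range(-search_radius_px, search_radius_px + 1):
        ov = ov0 - d  # displacement +d shrinks the true overlap
        if ov < min_overlap_px or ov > min(left.shape[-1], right.shape[-1]):
            continue
        a = left[..., -ov:]
        b = right[..., :ov]
        msd = float(np.mean((a - b) ** 2))
        all_msd.append(msd)
        if best is None or msd < best[1]:
            best = (d, msd, a, b, ov)
    if best is None:
        raise ValueError("no admissible overlap within the search window")
    d, msd, a, b, ov = best

    # undetermined registration: a statistically flat overlap, or an MSD
    # landscape with no pronounced minimum (uncorrelated content, where the
    # MSD sits near 2*sigma^2 at every shift)
    flat = max(float(np.var(a)), float(np.var(b))) <= var_eps and msd <= var_eps
    featureless = len(all_msd) > 2 and msd >= 0.5 * float(np.median(all_msd))
    if flat or featureless:
        warnings.warn(
            "overlap region carries no registration signal; using the "
            "nominal overlap and a center cut",
            stacklevel=2,
        )
        return 0, ov0 // 2

    col_msd = np.mean((a - b) ** 2, axis=tuple(range(a.ndim - 1)))
    lo = np.min(col_msd)
    candidates = np.nonzero(np.isclose(col_msd, lo))[0]
    center = (ov - 1) / 2.0
    cut = int(candidates[np.argmin(np.abs(candidates - center))])
    return -d, cut


def stitch(
    strips: list[np.ndarray],
    overlaps_px: list[int] | tuple[int, ...],
    cutlines: list[int] | None = None,
    feather_px: int = 0,
) -> tuple[np.ndarray, np.ndarray, tuple[int, ...]]:
    """Hard-concatenate left-to-right strips at their seam cutlines.

    ``cutlines[j]`` indexes the cut column within overlap j (defaults to the
    overlap center); the cut column itself is taken from the left strip.
    Returns ``(merged, provenance, cutlines_merged)`` where ``provenance``
    assigns every merged column to exactly one source strip and
    ``cutlines_merged`` are the seam positions in merged-frame columns.
    The merged width is always ``sum(widths) - sum(overlaps)``.
    """
    if len(strips) == 0:
        raise ValueError("nothing to stitch")
    strips = [np.asarray(s, dtype=float) for s in strips]
    lead_shape = strips[0].shape[:-1]
    for s in strips:
        if s.shape[:-1] != lead_shape:
            raise ValueError("all strips must agree in every non-lateral axis")
    if len(overlaps_px) != len(strips) - 1:
        raise ValueError("one overlap per seam required")
    if cutlines is None:
        cutlines = [ov // 2 for ov in overlaps_px]
    if len(cutlines) != len(overlaps_px):
        raise ValueError("one cutline per seam required")

    pieces = []
    prov = []
    seams: list[int] = []
    pos = 0
    for j, s in enumerate(strips):
        # drop the columns this strip contributes to the previous strip's
        # side of the seam (cut column included on the left side)
        start = cutlines[j - 1] + 1 if j > 0 else 0
        end = s.shape[-1]
        if j < len(strips) - 1:
            ov, cut = overlaps_px[j], cutlines[j]
            if not 0 <= cut < ov:
                raise ValueError(f"cutline {cut} outside overlap window [0, {ov})")
            end = s.shape[-1] - ov + cut + 1
        pieces.append(s[..., start:end])
        prov.append(np.full(end - start, j, dtype=int))
        pos += end - start
        if j < len(strips) - 1:
            seams.append(pos - 1)
    merged = np.concatenate(pieces, axis=-1)
    provenance = np.concatenate(prov)
    expected = sum(s.shape[-1] for s in strips) - sum(overlaps_px)
    if merged.shape[-1] != expected:
        raise AssertionError("stitch arithmetic violated")

    if feather_px > 0:
        # linear cross-fade of the two source strips across each seam
        offsets = np.concatenate([[0], np.cumsum([s.shape[-1] for s in strips])])
        starts = offsets[:-1] - np.concatenate([[0], np.cumsum(overlaps_px)])
        for j, seam in enumerate(seams):
            w = int(feather_px)
            lo, hi = max(seam - w + 1, 0), min(seam + w + 1, merged.shape[-1])
            t = (np.arange(lo, hi) - (seam + 0.5)) / (2.0 * w) + 0.5
            t = np.clip(t, 0.0, 1.0)
            lcols = np.arange(lo, hi) - starts[j]
            rcols = np.arange(lo, hi) - starts[j + 1]
            lvalid = lcols < strips[j].shape[-1]
            rvalid = rcols >= 0
            sel = lvalid & rvalid
            if not np.any(sel):
                continue
            lv = strips[j][..., lcols[sel]]
            rv = strips[j + 1][..., rcols[sel]]
            merged[..., np.arange(lo, hi)[sel]] = (1 - t[sel]) * lv + t[sel] * rv
    return merged, provenance, tuple(seams)


def flip_stitch_360(
    projections_0_to_360: np.ndarray,
    axis_offset_px: int,
    search_radius_px: int = 0,
) -> WideProjectionSet:
    """Fold a 360-degree off-center scan into wide 180-degree projections.

    The rotation axis sits at detector column ``W//2 + axis_offset_px``.
    For each angle ``theta`` in the first half rotation, the projection at
    ``theta + 180`` is horizontally flipped and stitched to the projection
    at ``theta`` about the axis; the result covers up to twice the detector
    width.  Requires an even projection count and a positive overlap between
    the flipped pair (the axis must remain on the detector).

    With ``search_radius_px > 0`` the pair is additionally registered by the
    mean-squared-difference cutline search before stitching, which absorbs a
    mis-stated axis position of up to that many pixels.
    """
    proj = np.asarray(projections_0_to_360, dtype=float)
    P = proj.shape[0]
    if P % 2:
        raise ValueError("a 360-degree scan needs an even projection count")
    W = proj.shape[-1]
    d = int(axis_offset_px)
    c = W // 2 + d  # axis column
    if not 0 <= c < W:
        raise ValueError("rotation axis lies outside the detector")
    half = P // 2
    first, second = proj[:half], proj[half:]
    flipped = second[..., ::-1]
    # in the theta frame: columns j of the theta projection sit at global
    # detector coordinates s = j - c; the flipped theta+180 projection
    # spans s in [c - W + 1, c] (its column m sits at s = c - W + 1 + m)
    start_orig, start_flip = -c, c - W + 1
    if start_orig <= start_flip:
        left, right = first, flipped
        left_start, right_start = start_orig, start_flip
    else:
        left, right = flipped, first
        left_start, right_start = start_flip, start_orig
    overlap = left_start + W - right_start
    if overlap <= 0:
        raise ValueError(
            "no overlap between the flipped projection pair; the rotation "
            "axis must remain on the detector"
        )
    cut = overlap // 2
    if search_radius_px > 0:
        shift, cut = find_cutline(
            left.reshape(half, -1, W).mean(axis=1),
            right.reshape(half, -1, W).mean(axis=1),
            overlap,
            search_radius_px,
        )
        overlap += shift
    merged, _, seams = stitch([left, right], [overlap], [cut])
    angles = np.arange(half) * (360.0 / P)
    return WideProjectionSet(
        projections=np.asarray(merged),
        angles_deg=angles,
        cutlines_px=seams,
        axis_col_px=-left_start,
    )


def merge_subscans(
    subscans: list[SubscanSet],
    geometry: ScanGeometry,
    search_radius_px: int = 0,
) -> WideProjectionSet:
    """Full merge: interpolate to a common count, register seams, stitch.

    Subscans must be ordered left to right (by lateral offset).  Each is
    first brought to the maximum projection count by angular interpolation;
    cutlines are then found per seam on the angle-mean strips and applied to
    every angle identically (the stage positions do not move between
    angles).
    """
    if len(subscans) != geometry.n_subscans:
        raise ValueError("one subscan per lateral position required")
    order = np.argsort([s.offset_px for s in subscans])
    subscans = [subscans[i] for i in order]
    target = max(s.n_projections for s in subscans)
    ups = [interpolate_missing(s, target) for s in subscans]
    for u in ups:
        if u.detector_width_px != geometry.detector_width_px:
            raise ValueError("subscan width does not match the scan geometry")

    cutlines: list[int] = []
    shifts: list[int] = []
    for j in range(len(ups) - 1):
        left = ups[j].projections.reshape(target, -1, ups[j].detector_width_px).mean(axis=1)
        right = ups[j + 1].projections.reshape(target, -1, ups[j + 1].detector_width_px).mean(axis=1)
        shift, cut = find_cutline(
            left, right, geometry.overlaps_px[j], search_radius_px
        )
        shifts.append(shift)
        cutlines.append(cut)

    merged, prov, seams = stitch(
        [u.projections for u in ups], list(geometry.overlaps_px), cutlines
    )
    return WideProjectionSet(
        projections=merged,
        angles_deg=ups[0].angles_deg,
        cutlines_px=seams,
        provenance=prov,
    )


def build_sinograms(wide: WideProjectionSet) -> SinogramStack:
    """Rearrange merged projections into per-slice sinograms.

    Sinogram n is row n of every merged projection in angle order.  For
    single-row (2-D) projection sets a single sinogram is produced.  Pure
    re-indexing: `sinograms_to_projections` inverts it bit-exactly.
    """
    proj = wide.projections
    if proj.ndim == 2:
        proj = proj[:, np.newaxis, :]
    if proj.ndim != 3:
        raise ValueError("projections must be [P, rows, width]")
    return SinogramStack(sinograms=np.ascontiguousarray(np.swapaxes(proj, 0, 1)))


def sinograms_to_projections(stack: SinogramStack) -> np.ndarray:
    """Inverse of `build_sinograms` (returns ``[P, rows, width]``)."""
    return np.ascontiguousarray(np.swapaxes(stack.sinograms, 0, 1))
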