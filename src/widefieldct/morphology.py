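"""Structural analysis of segmented airspace volumes.

Airway segments are extracted from gray-valued volumes by threshold-interval
region growing from a manually placed seed; small disconnected particles
inside the segmented lumen are removed by connected-component analysis, and
airspace dimensions are summarized by the histogram of the Euclidean
distance transform (per-voxel distance to the nearest background voxel, in
micrometres).  Keeping seed coordinates fixed across protocol volumes makes
the segmentations directly comparable.

Connectivity defaults to 26-neighbourhood (full 3x3x3) for both growing and
labeling; 6-connectivity is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "SegmentedRegion",
    "DistanceHistogram",
    "region_grow",
    "remove_small_components",
    "euclidean_distance_transform",
    "distance_histogram",
    "extract_roi",
]


def _structure(ndim: int, connectivity: int) -> np.ndarray:
    if connectivity == 26:
        return np.ones((3,) * ndim, dtype=bool)
    if connectivity == 6:
        return ndimage.generate_binary_structure(ndim, 1)
    raise ValueError("connectivity must be 6 or 26")


@dataclass
class SegmentedRegion:
    """A single connected in-interval component containing its seed."""

    mask: np.ndarray
    seed: tuple[int, ...]
    interval: tuple[float, float]


@dataclass
class DistanceHistogram:
    bin_edges_um: np.ndarray
    counts: np.ndarray
    roi_id: str = ""


def region_grow(
    volume: np.ndarray,
    seed: tuple[int, ...],
    interval: tuple[float, float],
    connectivity: int = 26,
) -> SegmentedRegion:
    """Threshold-interval region growing from a seed voxel.

    Returns the connected set of voxels reachable from the seed through
    voxels whose gray values lie within ``[low, high]``.  Deterministic;
    growing again from any voxel of the result reproduces it exactly.
    """
    vol = np.asarray(volume)
    seed = tuple(int(c) for c in seed)
    if len(seed) != vol.ndim or any(
        not 0 <= c < n for c, n in zip(seed, vol.shape)
    ):
        raise ValueError(f"seed {seed} outside the volume {vol.shape}")
    low, high = interval
    sval = vol[seed]
    if not low <= sval <= high:
        raise ValueError(
            f"seed value {sval} lies outside the interval [{low}, {high}]"
        )
    admissible = (vol >= low) & (vol <= high)
    labels, _ = ndimage.label(admissible, structure=_structure(vol.ndim, connectivity))
    mask = labels == labels[seed]
    return SegmentedRegion(mask=mask, seed=seed, interval=(float(low), float(high)))


def remove_small_components(
    mask: np.ndarray, min_voxels: int, connectivity: int = 26
) -> np.ndarray:
    """Drop connected components smaller than ``min_voxels`` voxels."""
    mask = np.asarray(mask).astype(bool)
    if min_voxels <= 1:
        return mask.copy()
    labels, n = ndimage.label(mask, structure=_structure(mask.ndim, connectivity))
    if n == 0:
        return mask.copy()
    counts = np.bincount(labels.ravel())
    keep = counts >= min_voxels
    keep[0] = False
    return keep[labels]


def euclidean_distance_transform(
    mask: np.ndarray, voxel_size_um: float = 1.0
) -> np.ndarray:
    """Per-voxel Euclidean distance (µm) to the nearest background voxel.

    Background voxels carry 0.  Requires at least one background voxel and
    isotropic voxels.
    """
    mask = np.asarray(mask).astype(bool)
    if voxel_size_um <= 0:
        raise ValueError("voxel size must be positive")
    if mask.all():
        raise ValueError(
            "all-foreground mask: no background voxel to measure distances to"
        )
    return ndimage.distance_transform_edt(mask) * voxel_size_um


def distance_histogram(
    distance_volume: np.ndarray,
    bin_width_um: float = 1.0,
    max_um: float | None = None,
    roi_id: str = "",
) -> DistanceHistogram:
    """Histogram of foreground distances; counts sum to the foreground size.

    Bins are ``[0, w), [w, 2w), ...`` up to ``max_um`` (default: past the
    largest observed distance); zero-distance (background) voxels are not
    counted.
    """
    if bin_width_um <= 0:
        raise ValueError("bin width must be positive")
    d = np.asarray(distance_volume, dtype=float)
    fg = d[d > 0]
    if max_um is None:
        top = float(fg.max()) if fg.size else bin_width_um
        max_um = (np.floor(top / bin_width_um) + 1) * bin_width_um
    edges = np.arange(0.0, max_um + bin_width_um * 0.5, bin_width_um)
    counts, _ = np.histogram(fg, bins=edges)
    # distances beyond the last edge still belong to the foreground census
    overflow = int((fg >= edges[-1]).sum())
    counts[-1] += overflow
    return DistanceHistogram(bin_edges_um=edges, counts=counts, roi_id=roi_id)


def extract_roi(
    volume: np.ndarray, corner: tuple[int, ...], size: int
) -> np.ndarray:
    """Cubic region of interest; pure cropping, gray values untouched."""
    vol = np.asarray(volume)
    sl = []
    for c, n in zip(corner, vol.shape):
        if not 0 <= c <= n - size:
            raise ValueError(f"ROI corner {corner} with size {size} exceeds {vol.shape}")
        sl.append(slice(c, c + size))
    return vol[tuple(sl)].copy()
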