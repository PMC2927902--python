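"""Synthetic data: phantoms, offset subscan projections, flats and darks.

The simulator stands in for the beamline.  A phantom (by default the
canonical 10-ellipse Shepp–Logan head section) is forward-projected in
parallel-beam geometry; each subscan observes only the lateral detector band
``[offset - D/2, offset + D/2)`` around its center, exactly as a small
detector at a laterally displaced sample position would.  Flat (beam on, no
sample) and dark (beam off) frames are generated so the normalization stage
has realistic inputs.

Coordinate conventions, shared with the merge and recon stages:

* the rotation axis passes through the image center; the signed detector
  coordinate ``s`` is 0 on the axis;
* angles are in degrees; at ``theta = 0`` the detector coordinate equals the
  image x-coordinate, and increasing ``theta`` rotates the projection
  direction so that at 90 degrees it equals the (upward) y-coordinate;
* projection rows are line integrals in units of attenuation x pixel size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.transform import radon

__all__ = [
    "Phantom",
    "SubscanSet",
    "SHEPP_LOGAN_ELLIPSES",
    "shepp_logan",
    "disc_phantom",
    "forward_project",
    "wide_projection",
    "mirror_profile",
    "make_flats_darks",
    "add_gaussian_noise",
]


def mirror_profile(profile: np.ndarray) -> np.ndarray:
    """Mirror a detector profile about the rotation axis (index ``w//2``).

    For parallel-beam data the profile at ``theta + 180`` degrees is the
    axis-mirrored profile at ``theta``.  With the axis at index ``w//2`` the
    mirror is a flip for odd widths and a flip-plus-roll for even widths
    (the single wrapped edge pixel lies outside the sample support).
    """
    flipped = profile[..., ::-1]
    if profile.shape[-1] % 2 == 0:
        flipped = np.roll(flipped, 1, axis=-1)
    return flipped

# Canonical head-phantom parameters: (x0, y0, a, b, phi_deg, gray).
# Positions and half-axes are in the unit square [-1, 1]^2; gray values are
# additive.  The low-contrast interior (0.01-0.02 steps on a ~1.02 base) is
# part of the canon.
SHEPP_LOGAN_ELLIPSES: tuple[tuple[float, float, float, float, float, float], ...] = (
    (0.0, 0.0, 0.69, 0.92, 0.0, 2.0),
    (0.0, -0.0184, 0.6624, 0.874, 0.0, -0.98),
    (0.22, 0.0, 0.11, 0.31, -18.0, -0.02),
    (-0.22, 0.0, 0.16, 0.41, 18.0, -0.02),
    (0.0, 0.35, 0.21, 0.25, 0.0, 0.01),
    (0.0, 0.1, 0.046, 0.046, 0.0, 0.01),
    (0.0, -0.1, 0.046, 0.046, 0.0, 0.01),
    (-0.08, -0.605, 0.046, 0.023, 0.0, 0.01),
    (0.0, -0.605, 0.023, 0.023, 0.0, 0.01),
    (0.06, -0.605, 0.023, 0.046, 0.0, 0.01),
)


@dataclass(frozen=True)
class Phantom:
    """A square attenuation image whose support fits the inscribed circle."""

    image: np.ndarray
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        img = np.asarray(self.image, dtype=float)
        if img.ndim not in (2, 3):
            raise ValueError("phantom must be a 2-D image or a 3-D stack")
        if img.shape[-1] != img.shape[-2]:
            raise ValueError("phantom must be square in-plane")
        if not np.all(np.isfinite(img)):
            raise ValueError("phantom values must be finite")
        object.__setattr__(self, "image", img)

    @property
    def width_px(self) -> int:
        return self.image.shape[-1]


@dataclass
class SubscanSet:
    """Projections, angles and correction frames of one lateral subscan."""

    projections: np.ndarray  # [P, detector_width] or [P, rows, detector_width]
    angles_deg: np.ndarray
    offset_px: int = 0
    darks: np.ndarray | None = None
    flats: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.projections = np.asarray(self.projections, dtype=float)
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        if self.projections.shape[0] != self.angles_deg.shape[0]:
            raise ValueError("one projection per angle required")
        d = np.diff(self.angles_deg)
        if d.size and (np.any(d <= 0) or not np.allclose(d, d[0])):
            raise ValueError("angles must be strictly increasing and equiangular")
        for frames in (self.darks, self.flats):
            if frames is not None and frames.shape[-1] != self.detector_width_px:
                raise ValueError("dark/flat width must match the projections")

    @property
    def n_projections(self) -> int:
        return int(self.projections.shape[0])

    @property
    def detector_width_px(self) -> int:
        return int(self.projections.shape[-1])


def _ellipse_image(width_px: int, ellipses) -> np.ndarray:
    w = width_px
    # pixel centers on the unit square; the rotation axis sits at index
    # w//2 (the rotation center of the projector), y increases upward
    coords = (np.arange(w) - w // 2) / (w / 2.0)
    x = coords[np.newaxis, :]
    y = -coords[:, np.newaxis]
    img = np.zeros((w, w))
    for (x0, y0, a, b, phi_deg, gray) in ellipses:
        phi = np.deg2rad(phi_deg)
        xr = (x - x0) * np.cos(phi) + (y - y0) * np.sin(phi)
        yr = -(x - x0) * np.sin(phi) + (y - y0) * np.cos(phi)
        img[(xr / a) ** 2 + (yr / b) ** 2 <= 1.0] += gray
    return img


def shepp_logan(width_px: int, pixel_size_um: float = 1.0) -> Phantom:
    """The canonical 10-ellipse Shepp–Logan head phantom at ``width_px``.

    Deterministic; a pixel's value is the sum of the gray levels of every
    ellipse containing the pixel center.
    """
    if width_px < 16:
        raise ValueError("phantom width must be at least 16 px")
    return Phantom(_ellipse_image(width_px, SHEPP_LOGAN_ELLIPSES), pixel_size_um)


def disc_phantom(
    width_px: int,
    radius_px: float,
    value: float = 1.0,
    center_px: tuple[float, float] = (0.0, 0.0),
    pixel_size_um: float = 1.0,
    supersample: int = 4,
) -> Phantom:
    """Uniform disc of ``value``; center offset (x, y) in pixels from the axis.

    Edge pixels carry their covered-area fraction (``supersample``-fold
    subpixel sampling), so line integrals approach the analytic chord
    length ``2*sqrt(r^2 - s^2)*value``.
    """
    w = width_px
    c = w // 2  # rotation-axis pixel
    n = max(1, int(supersample))
    sub = (np.arange(n) + 0.5) / n - 0.5
    yy, xx = np.mgrid[0:w, 0:w]
    acc = np.zeros((w, w))
    for dy in sub:
        for dx in sub:
            x = xx + dx - c - center_px[0]
            y = -(yy + dy - c) - center_px[1]
            acc += x**2 + y**2 <= radius_px**2
    return Phantom(acc / n**2 * float(value), pixel_size_um)


def wide_projection(phantom: Phantom, angles_deg) -> np.ndarray:
    """Full-width parallel-beam projections of a 2-D phantom.

    Returns an array ``[P, width_px]``; row p is the line-integral profile at
    ``angles_deg[p]`` in attenuation x pixel-size units over the full
    phantom width (detector index ``width//2`` sits on the rotation axis).
    """
    img = phantom.image
    if img.ndim != 2:
        raise ValueError("wide_projection expects a 2-D phantom")
    angles = np.asarray(angles_deg, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # support-circle warning
        sino = radon(img, theta=angles, circle=True)
    return sino.T * phantom.pixel_size_um


def forward_project(
    phantom: Phantom,
    angles_deg,
    offset_px: int,
    detector_width_px: int,
) -> SubscanSet:
    """Simulate one subscan: the detector band around ``offset_px``.

    The subscan samples rays at global detector coordinates
    ``s in [offset - W/2, offset + W/2)``.  Bands outside the phantom are
    zero-padded; a band with no overlap at all triggers a warning and
    all-zero rows.
    """
    W = int(detector_width_px)
    if W < 1:
        raise ValueError("detector width must be positive")
    angles = np.atleast_1d(np.asarray(angles_deg, dtype=float))
    wide = wide_projection(phantom, angles)
    full = wide.shape[1]
    center = full // 2
    lo = center + int(offset_px) - W // 2
    hi = lo + W
    rows = np.zeros((angles.shape[0], W))
    src_lo, src_hi = max(lo, 0), min(hi, full)
    if src_lo >= src_hi:
        warnings.warn(
            f"subscan band [{lo}, {hi}) lies outside the phantom support",
            stacklevel=2,
        )
    else:
        rows[:, src_lo - lo : src_hi - lo] = wide[:, src_lo:src_hi]
    return SubscanSet(projections=rows, angles_deg=angles, offset_px=int(offset_px))


def make_flats_darks(
    detector_width_px: int,
    n: int,
    flat_level: float,
    dark_level: float,
    noise_sd: float,
    seed: int,
    n_rows: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian flat/dark frame stacks, shape ``[n, n_rows, width]``.

    Flats model the blank beam, darks the detector offset; both are
    reproducible for a given seed.
    """
    if flat_level <= dark_level:
        raise ValueError("flat level must exceed dark level")
    if dark_level < 0 or noise_sd < 0:
        raise ValueError("levels and noise sd must be non-negative")
    rng = np.random.default_rng(seed)
    shape = (n, n_rows, detector_width_px)
    flats = rng.normal(flat_level, noise_sd, shape) if noise_sd else np.full(shape, float(flat_level))
    darks = rng.normal(dark_level, noise_sd, shape) if noise_sd else np.full(shape, float(dark_level))
    return flats, darks


def add_gaussian_noise(image: np.ndarray, sd: float, seed: int) -> np.ndarray:
    """Additive white Gaussian noise; ``sd = 0`` returns the input unchanged."""
    if sd < 0:
        raise ValueError("noise sd must be non-negative")
    image = np.asarray(image, dtype=float)
    if sd == 0:
        return image.copy()
    rng = np.random.default_rng(seed)
    return image + rng.normal(0.0, sd, image.shape)


def to_transmittance(
    subscan: SubscanSet,
    flat_level: float = 1.0,
    dark_level: float = 0.0,
    attenuation_scale: float = 1.0,
) -> np.ndarray:
    """Map absorption-domain projections to detector counts.

    ``I = flat * exp(-mu * scale) + dark`` — the inverse of the flat/dark
    normalization followed by a negative log.
    """
    mu = subscan.projections * attenuation_scale
    return flat_level * np.exp(-mu) + dark_level
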