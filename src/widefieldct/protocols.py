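"""Scan-protocol planning for wide-field parallel-beam tomography.

A detector of width ``D`` pixels needs about ``P = D*pi/2`` equiangular
projections over 180 degrees to satisfy the CT sampling theorem.  Covering a
field of view wider than the detector is done with an odd number of laterally
offset 180-degree subscans (one central scan plus pairs of half ring-scans)
whose projections are later merged.  Because the lateral subscans sweep the
widest annulus, they set the projection requirement; the central subscan may
be acquired with fewer projections (the same count or half of it) and the
missing angles interpolated, which cuts acquisition time and hence radiation
dose without a matching loss of reconstruction quality.

This module does the arithmetic: projection requirements, subscan layout,
the reference ("gold standard") projection total, and ladders of
dose-reduced acquisition protocols.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "ScanGeometry",
    "Protocol",
    "required_projections",
    "plan_widefield",
    "reference_total",
    "reference_per_subscan",
    "make_protocol_ladder",
    "dose_reduction_pct",
    "fov_mm",
    "TABLE1",
    "ladder_to_text",
]


def _round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class ScanGeometry:
    """Lateral layout of a wide-field scan.

    The global detector coordinate ``s`` is signed, with ``s = 0`` on the
    rotation axis.  Subscan ``i`` samples the band
    ``[offset_i - D/2, offset_i + D/2)``; adjacent bands overlap by
    ``overlaps_px`` to allow cutline-based stitching.
    """

    detector_width_px: int
    pixel_size_um: float
    n_subscans: int
    offsets_px: tuple[int, ...]
    overlaps_px: tuple[int, ...]
    desired_fov_px: int

    def __post_init__(self) -> None:
        D = self.detector_width_px
        if D <= 0:
            raise ValueError("detector width must be positive")
        if self.n_subscans < 1 or self.n_subscans % 2 == 0:
            raise ValueError("n_subscans must be an odd integer >= 1")
        if len(self.offsets_px) != self.n_subscans:
            raise ValueError("one lateral offset per subscan required")
        if len(self.overlaps_px) != self.n_subscans - 1:
            raise ValueError("n_subscans - 1 overlaps required")
        for ov in self.overlaps_px:
            if not 0 <= ov < D:
                raise ValueError(
                    f"overlap {ov} px outside [0, detector width {D})"
                )
        if sorted(self.offsets_px) != sorted(-o for o in self.offsets_px):
            raise ValueError("offsets must be symmetric about the rotation axis")
        if self.n_subscans % 2 == 1 and 0 not in self.offsets_px:
            raise ValueError("central subscan must sit on the rotation axis")
        if self.covered_width_px < self.desired_fov_px:
            raise ValueError(
                f"covered width {self.covered_width_px} px cannot reach the "
                f"desired field of view {self.desired_fov_px} px"
            )

    @property
    def covered_width_px(self) -> int:
        """Width of the merged projection: ``n*D - sum(overlaps)``."""
        return self.n_subscans * self.detector_width_px - sum(self.overlaps_px)

    @property
    def covered_fov_mm(self) -> float:
        return fov_mm(self.covered_width_px, self.pixel_size_um)


@dataclass(frozen=True)
class Protocol:
    """One acquisition protocol: per-subscan projection counts and dose.

    ``merged_projection_count`` is the angular sampling of the merged
    projection set (the maximum over the subscans); subscans acquired with
    fewer projections are brought up to it by angular interpolation, which is
    only allowed for power-of-two count ratios.
    """

    label: str
    per_subscan_projections: tuple[int, ...]
    total_projections: int = field(init=False)
    merged_projection_count: int = field(init=False)
    dose_fraction_pct: int | None = None

    def __post_init__(self) -> None:
        counts = self.per_subscan_projections
        if not counts or any(c < 1 for c in counts):
            raise ValueError("per-subscan projection counts must be >= 1")
        top = max(counts)
        for c in counts:
            r = max(1, _round_half_away(top / c))
            # the count must raise to the merged count by a power-of-two
            # factor; one count of slack absorbs half-multiple rounding
            if (r & (r - 1)) or abs(r * c - top) > 1:
                raise ValueError(
                    f"subscan count {c} must equal the merged count {top} "
                    "or divide it by a power of two"
                )
        object.__setattr__(self, "total_projections", int(sum(counts)))
        object.__setattr__(self, "merged_projection_count", int(top))


def required_projections(width_px: float) -> float:
    """Projections needed for a width of ``width_px`` pixels: ``w*pi/2``.

    The value is returned unrounded; round only final reported totals.

    >>> round(required_projections(3072))
    4825
    """
    if width_px < 0:
        raise ValueError("width must be non-negative")
    return width_px * math.pi / 2.0


def plan_widefield(
    desired_fov_px: int,
    detector_width_px: int,
    overlap_px: int,
    pixel_size_um: float = 1.0,
) -> ScanGeometry:
    """Lay out the smallest odd number of subscans covering a desired FOV.

    Subscan centers are spaced by ``detector_width - overlap`` and placed
    symmetrically about the rotation axis, giving one central scan and
    ``(n-1)/2`` pairs of half ring-scans.
    """
    D = int(detector_width_px)
    if desired_fov_px < D:
        raise ValueError("desired field of view must be at least one detector width")
    if not 0 <= overlap_px < D:
        raise ValueError(f"overlap must lie in [0, detector width {D})")
    n = 1
    while n * D - (n - 1) * overlap_px < desired_fov_px:
        n += 2
    pitch = D - overlap_px
    half = n // 2
    offsets = tuple(k * pitch for k in range(-half, half + 1))
    return ScanGeometry(
        detector_width_px=D,
        pixel_size_um=pixel_size_um,
        n_subscans=n,
        offsets_px=offsets,
        overlaps_px=(overlap_px,) * (n - 1),
        desired_fov_px=int(desired_fov_px),
    )


def reference_total(geometry: ScanGeometry) -> int:
    """Projection total of the gold-standard protocol for ``geometry``.

    Every subscan acquires enough projections for the full covered width, so
    the total is ``round(n * covered_width * pi/2)`` — e.g. 13534 for three
    1024-px subscans with 100-px overlaps (covered width 2872).
    """
    return _round_half_away(
        geometry.n_subscans * required_projections(geometry.covered_width_px)
    )


def reference_per_subscan(geometry: ScanGeometry) -> int:
    """Gold-standard projections per subscan (= merged projection count)."""
    return _round_half_away(required_projections(geometry.covered_width_px))


def make_protocol_ladder(
    geometry: ScanGeometry,
    base_unit: int,
    steps: list[tuple[float, ...]],
    labels: list[str] | None = None,
) -> list[Protocol]:
    """Build a ladder of protocols from per-subscan multiples of a base unit.

    Each step assigns every subscan a multiple (integers or half-integers) of
    ``base_unit``; counts are rounded to the nearest integer.  The central
    subscan's count must equal the lateral count or half of it, so that
    merging needs at most a factor-of-two angular interpolation.  Dose
    fractions are percentages of the geometry's gold-standard total.
    """
    if base_unit < 1:
        raise ValueError("base unit must be >= 1")
    ref = reference_total(geometry)
    if labels is None:
        labels = [chr(ord("B") + i) for i in range(len(steps))]
    if len(labels) != len(steps):
        raise ValueError("one label per step required")
    ladder: list[Protocol] = []
    for label, step in zip(labels, steps):
        if len(step) != geometry.n_subscans:
            raise ValueError(
                f"step {step} must give one multiple per subscan "
                f"({geometry.n_subscans})"
            )
        lateral = step[0]
        for m in step:
            if m <= 0:
                raise ValueError("multiples must be positive")
        central = step[geometry.n_subscans // 2]
        if not (central == lateral or 2 * central == lateral):
            raise ValueError(
                f"central multiple {central} must equal the lateral multiple "
                f"{lateral} or half of it"
            )
        lateral_count = _round_half_away(lateral * base_unit)
        counts = tuple(
            _round_half_away(lateral_count / 2.0)
            if 2 * m == lateral
            else _round_half_away(m * base_unit)
            for m in step
        )
        proto = Protocol(label=label, per_subscan_projections=counts)
        object.__setattr__(
            proto,
            "dose_fraction_pct",
            _round_half_away(100.0 * proto.total_projections / ref),
        )
        ladder.append(proto)
    return ladder


def dose_reduction_pct(protocol: Protocol, reference: int) -> int:
    """Dose/time saving of ``protocol`` vs the reference total, in percent.

    Dose is modeled as proportional to the number of acquired projections;
    a protocol exceeding the reference yields a negative reduction.
    """
    if reference <= 0:
        raise ValueError("reference total must be positive")
    return _round_half_away(100.0 * (1.0 - protocol.total_projections / reference))


def fov_mm(width_px: float, pixel_size_um: float) -> float:
    """Field of view in millimetres, reported to 2 decimals."""
    if width_px < 0 or pixel_size_um < 0:
        raise ValueError("width and pixel size must be non-negative")
    return round(width_px * pixel_size_um / 1000.0, 2)


#: Printed per-protocol values of the published 19-protocol study (labels,
#: per-subscan projection counts s1/s2/s3, total, dose % and simulated
#: quality %), recorded verbatim.  The printed table carries occasional +/-1
#: rounding inconsistencies relative to exact multiples of the 874-projection
#: base unit (e.g. 2186 vs 2185); `make_protocol_ladder` follows exact
#: nearest-integer arithmetic instead.
TABLE1: tuple[dict, ...] = (
    {"label": "A", "s": None, "total": 13534, "dose_pct": 100, "quality_pct": None},
    {"label": "B", "s": (5244, 5244, 5244), "total": 15732, "dose_pct": 116, "quality_pct": 100},
    {"label": "C", "s": (5244, 2622, 5244), "total": 13110, "dose_pct": 97, "quality_pct": 89},
    {"label": "D", "s": (4370, 4370, 4370), "total": 13110, "dose_pct": 97, "quality_pct": 85},
    {"label": "E", "s": (4370, 2185, 4370), "total": 10925, "dose_pct": 81, "quality_pct": 87},
    {"label": "F", "s": (3934, 3934, 3934), "total": 11802, "dose_pct": 87, "quality_pct": 80},
    {"label": "G", "s": (3934, 1967, 3934), "total": 9835, "dose_pct": 73, "quality_pct": 84},
    {"label": "H", "s": (3496, 3496, 3496), "total": 10488, "dose_pct": 77, "quality_pct": 78},
    {"label": "I", "s": (3496, 1748, 3496), "total": 8740, "dose_pct": 65, "quality_pct": 80},
    {"label": "J", "s": (3060, 3060, 3060), "total": 9180, "dose_pct": 68, "quality_pct": 76},
    {"label": "K", "s": (3060, 1530, 3060), "total": 7650, "dose_pct": 57, "quality_pct": 75},
    {"label": "L", "s": (2622, 2622, 2622), "total": 7866, "dose_pct": 58, "quality_pct": 72},
    {"label": "M", "s": (2622, 1311, 2622), "total": 6555, "dose_pct": 48, "quality_pct": 69},
    {"label": "N", "s": (2186, 2186, 2186), "total": 6558, "dose_pct": 48, "quality_pct": 67},
    {"label": "O", "s": (2185, 1093, 2185), "total": 5463, "dose_pct": 40, "quality_pct": 62},
    {"label": "P", "s": (1748, 1748, 1748), "total": 5244, "dose_pct": 39, "quality_pct": 61},
    {"label": "Q", "s": (1748, 874, 1748), "total": 4370, "dose_pct": 32, "quality_pct": 55},
    {"label": "R", "s": (1312, 1312, 1312), "total": 3936, "dose_pct": 29, "quality_pct": 46},
    {"label": "S", "s": (874, 874, 874), "total": 2622, "dose_pct": 19, "quality_pct": 21},
    {"label": "T", "s": (874, 437, 874), "total": 2185, "dose_pct": 16, "quality_pct": 20},
)


def ladder_to_text(geometry: ScanGeometry, ladder: list[Protocol]) -> str:
    """Serialize a ladder to the plain-text preference-file dialect.

    One section per protocol: label, per-subscan counts, offsets; readable
    as YAML.
    """
    ref = reference_total(geometry)
    lines = [
        "geometry:",
        f"  detector_width_px: {geometry.detector_width_px}",
        f"  pixel_size_um: {geometry.pixel_size_um}",
        f"  n_subscans: {geometry.n_subscans}",
        f"  offsets_px: {list(geometry.offsets_px)}",
        f"  overlaps_px: {list(geometry.overlaps_px)}",
        f"  covered_width_px: {geometry.covered_width_px}",
        f"  reference_total: {ref}",
        "protocols:",
    ]
    for p in ladder:
        lines += [
            f"  - label: {p.label}",
            f"    per_subscan_projections: {list(p.per_subscan_projections)}",
            f"    total_projections: {p.total_projections}",
            f"    merged_projection_count: {p.merged_projection_count}",
            f"    dose_fraction_pct: {p.dose_fraction_pct}",
        ]
    return "\n".join(lines) + "\n"
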