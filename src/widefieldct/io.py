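"""On-disk layout: 16-bit grayscale TIFF stacks plus YAML scan logs.

A subscan directory holds ``proj_0000.tif ...``, ``flat_0000.tif ...``,
``dark_0000.tif ...`` and a ``scanlog.yml`` naming the angles, the lateral
offset and the float->uint16 scaling used for the projections, so stacks
round-trip through disk without losing the physical scale.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile
import yaml

from .phantom_sim import SubscanSet

__all__ = [
    "write_tiff_stack",
    "read_tiff_stack",
    "write_subscan_dir",
    "read_subscan_dir",
    "write_wide_stack",
    "read_wide_stack",
]

_U16 = np.iinfo(np.uint16).max


def _scale_to_uint16(stack: np.ndarray) -> tuple[np.ndarray, float, float]:
    lo = float(stack.min())
    hi = float(stack.max())
    span = hi - lo if hi > lo else 1.0
    q = np.round((stack - lo) / span * _U16).astype(np.uint16)
    return q, lo, span


def write_tiff_stack(
    directory: Path, prefix: str, stack: np.ndarray
) -> dict:
    """Write ``stack[k]`` as ``<prefix>_<k:04d>.tif``; returns the scaling."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stack = np.asarray(stack, dtype=float)
    q, lo, span = _scale_to_uint16(stack)
    for k in range(q.shape[0]):
        tifffile.imwrite(directory / f"{prefix}_{k:04d}.tif", np.atleast_2d(q[k]))
    return {"offset": lo, "scale": span / _U16, "count": int(q.shape[0])}


def read_tiff_stack(directory: Path, prefix: str, scaling: dict) -> np.ndarray:
    directory = Path(directory)
    frames = [
        tifffile.imread(p).astype(float)
        for p in sorted(directory.glob(f"{prefix}_*.tif"))
    ]
    if len(frames) != scaling["count"]:
        raise ValueError(
            f"expected {scaling['count']} {prefix} frames, found {len(frames)}"
        )
    stack = np.stack(frames, axis=0)
    return stack * scaling["scale"] + scaling["offset"]


def write_subscan_dir(directory: Path, subscan: SubscanSet) -> None:
    """Write a subscan (projections, darks, flats, scan log) to a directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    log: dict = {
        "offset_px": int(subscan.offset_px),
        "angles_deg": [float(a) for a in subscan.angles_deg],
    }
    log["projections"] = write_tiff_stack(directory, "proj", subscan.projections)
    if subscan.darks is not None:
        log["darks"] = write_tiff_stack(directory, "dark", subscan.darks)
    if subscan.flats is not None:
        log["flats"] = write_tiff_stack(directory, "flat", subscan.flats)
    (directory / "scanlog.yml").write_text(yaml.safe_dump(log, sort_keys=False))


def read_subscan_dir(directory: Path) -> SubscanSet:
    directory = Path(directory)
    log = yaml.safe_load((directory / "scanlog.yml").read_text())
    proj = read_tiff_stack(directory, "proj", log["projections"])
    if proj.shape[1] == 1:  # single-row projections stored as 1-px-high TIFFs
        proj = proj[:, 0, :]
    darks = flats = None
    if "darks" in log:
        darks = read_tiff_stack(directory, "dark", log["darks"])
    if "flats" in log:
        flats = read_tiff_stack(directory, "flat", log["flats"])
    return SubscanSet(
        projections=proj,
        angles_deg=np.asarray(log["angles_deg"], dtype=float),
        offset_px=int(log["offset_px"]),
        darks=darks,
        flats=flats,
    )


def write_wide_stack(directory: Path, projections: np.ndarray, angles_deg) -> None:
    """Write merged wide projections plus their log."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    log = {
        "angles_deg": [float(a) for a in np.asarray(angles_deg)],
        "projections": write_tiff_stack(directory, "merged", projections),
    }
    (directory / "mergelog.yml").write_text(yaml.safe_dump(log, sort_keys=False))


def read_wide_stack(directory: Path) -> tuple[np.ndarray, np.ndarray]:
    directory = Path(directory)
    log = yaml.safe_load((directory / "mergelog.yml").read_text())
    proj = read_tiff_stack(directory, "merged", log["projections"])
    if proj.shape[1] == 1:
        proj = proj[:, 0, :]
    return proj, np.asarray(log["angles_deg"], dtype=float)
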