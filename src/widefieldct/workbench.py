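"""Run orchestration: a config-driven plan -> simulate -> merge ->
reconstruct -> evaluate -> morph pipeline.

A run is fully described by one YAML config plus a seed; every stage writes
into its own subdirectory of the run directory, records a manifest with
SHA-256 digests of its outputs, and drops a ``.done`` marker so a partial
rerun resumes from existing stage outputs.  Stages never modify another
stage's directory.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as _io
from . import merge as _merge
from . import morphology as _morph
from . import phantom_sim as _sim
from . import quality as _quality
from . import recon as _recon
from . import protocols as _protocols

__all__ = ["RunConfig", "run_pipeline"]

_STAGES = ("plan", "simulate", "merge", "reconstruct", "evaluate", "morph")


@dataclass
class RunConfig:
    """Validated, serializable description of one pipeline run."""

    out_dir: str
    seed: int = 0
    desired_fov_px: int = 384
    detector_width_px: int = 144
    overlap_px: int = 24
    pixel_size_um: float = 1.48
    base_unit: int = 120
    steps: list = field(
        default_factory=lambda: [(5, 5, 5), (3, 3, 3), (1, 0.5, 1)]
    )
    labels: list | None = None
    protocols_to_run: list | None = None  # default: all ladder rungs
    noise_sd: float = 0.02
    transmittance: bool = False  # write detector counts instead of line integrals
    attenuation_scale: float = 0.005  # per-pixel absorption scale in that mode
    filter_name: str = "ram-lak"
    search_radius_px: int = 0
    stride: int = 1
    stages: list = field(default_factory=lambda: list(_STAGES[:5]))
    morph_interval: tuple | None = None
    morph_seed_px: tuple | None = None
    morph_bin_width_um: float = 1.0
    morph_min_voxels: int = 1

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")
        # geometry validity (overlap vs detector width etc.) is checked by
        # constructing the geometry up front
        self.geometry()
        self.ladder()

    @classmethod
    def from_yaml(cls, path: Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(**raw)

    def to_yaml(self) -> str:
        d = dict(self.__dict__)
        d["steps"] = [list(s) for s in self.steps]
        return yaml.safe_dump(d, sort_keys=False)

    def geometry(self) -> _protocols.ScanGeometry:
        return _protocols.plan_widefield(
            self.desired_fov_px,
            self.detector_width_px,
            self.overlap_px,
            self.pixel_size_um,
        )

    def ladder(self) -> list[_protocols.Protocol]:
        return _protocols.make_protocol_ladder(
            self.geometry(),
            self.base_unit,
            [tuple(s) for s in self.steps],
            self.labels,
        )


def _digest_dir(directory: Path) -> dict:
    out = {}
    for p in sorted(directory.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            out[str(p.relative_to(directory))] = hashlib.sha256(
                p.read_bytes()
            ).hexdigest()
    return out


def _finish_stage(stage_dir: Path, params: dict) -> None:
    manifest = {"params": params, "digests": _digest_dir(stage_dir)}
    (stage_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    (stage_dir / ".done").touch()


def run_pipeline(config: RunConfig) -> Path:
    """Execute the enabled stages in order; returns the run directory.

    A stage whose directory carries a ``.done`` marker is skipped, so an
    interrupted run resumes where it stopped.  Any stage failure aborts the
    run with the failing stage named.
    """
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    (run_dir / "config.yml").write_text(config.to_yaml())

    geometry = config.geometry()
    ladder = config.ladder()
    selected = config.protocols_to_run or [p.label for p in ladder]
    by_label = {p.label: p for p in ladder}
    missing = [l for l in selected if l not in by_label]
    if missing:
        raise ValueError(f"protocols {missing} not in the ladder")

    for stage in [s for s in _STAGES if s in config.stages]:
        stage_dir = run_dir / stage
        if (stage_dir / ".done").exists():
            continue
        stage_dir.mkdir(exist_ok=True)
        try:
            _run_stage(stage, stage_dir, run_dir, config, geometry, ladder, selected)
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    return run_dir


def _run_stage(stage, stage_dir, run_dir, config, geometry, ladder, selected):
    if stage == "plan":
        (stage_dir / "ladder.yml").write_text(
            _protocols.ladder_to_text(geometry, ladder)
        )
        _finish_stage(stage_dir, {"base_unit": config.base_unit})

    elif stage == "simulate":
        width = geometry.covered_width_px
        ref = _sim.shepp_logan(width, config.pixel_size_um).image
        ref = _sim.add_gaussian_noise(ref, config.noise_sd, config.seed)
        np.save(stage_dir / "reference.npy", ref)
        phantom = _sim.Phantom(ref, config.pixel_size_um)
        for label in selected:
            proto = [p for p in ladder if p.label == label][0]
            for i, (P, off) in enumerate(
                zip(proto.per_subscan_projections, geometry.offsets_px)
            ):
                angles = np.arange(P) * (180.0 / P)
                sub = _sim.forward_project(
                    phantom, angles, off, geometry.detector_width_px
                )
                if config.transmittance:
                    flats, darks = _sim.make_flats_darks(
                        geometry.detector_width_px,
                        n=4,
                        flat_level=1.0,
                        dark_level=0.05,
                        noise_sd=0.0,
                        seed=config.seed + i,
                    )
                    sub.projections = _sim.to_transmittance(
                        sub, 1.0, 0.05, config.attenuation_scale
                    )
                    sub.flats, sub.darks = flats, darks
                _io.write_subscan_dir(stage_dir / label / f"s{i}", sub)
        _finish_stage(stage_dir, {"noise_sd": config.noise_sd, "seed": config.seed})

    elif stage == "merge":
        sim_dir = run_dir / "simulate"
        for label in selected:
            subs = [
                _io.read_subscan_dir(d)
                for d in sorted((sim_dir / label).iterdir())
                if d.is_dir()
            ]
            if config.transmittance:
                # normalize first, then back to the absorption domain
                for sub in subs:
                    corrected = _merge.normalize(
                        sub.projections, sub.darks, sub.flats
                    )
                    sub.projections = (
                        -np.log(np.clip(corrected, 1e-9, None))
                        / config.attenuation_scale
                    )
            wide = _merge.merge_subscans(subs, geometry, config.search_radius_px)
            _io.write_wide_stack(stage_dir / label, wide.projections, wide.angles_deg)
        _finish_stage(stage_dir, {"search_radius_px": config.search_radius_px})

    elif stage == "reconstruct":
        for label in selected:
            proj, angles = _io.read_wide_stack(run_dir / "merge" / label)
            stack = _merge.build_sinograms(
                _merge.WideProjectionSet(projections=proj, angles_deg=angles)
            )
            slices = _recon.reconstruct_volume(
                stack, angles, config.filter_name, config.pixel_size_um
            )
            vol = np.stack([s.image for s in slices])
            np.save(stage_dir / f"{label}.npy", vol)
        _finish_stage(stage_dir, {"filter": config.filter_name})

    elif stage == "evaluate":
        rec_dir = run_dir / "reconstruct"
        ref = np.load(run_dir / "simulate" / "reference.npy")
        ref_bin = _quality.binarize(ref)
        rows = ["protocol\ttotal_projections\tdose_pct\tE"]
        errors, doses = [], []
        for label in selected:
            proto = [p for p in ladder if p.label == label][0]
            vol = np.load(rec_dir / f"{label}.npy")
            e = float(
                np.mean(
                    [
                        _quality.slice_difference(_quality.binarize(s), ref_bin)
                        for s in vol[:: config.stride]
                    ]
                )
            )
            errors.append(e)
            doses.append(float(proto.dose_fraction_pct))
            rows.append(
                f"{label}\t{proto.total_projections}\t{proto.dose_fraction_pct}\t{e}"
            )
        report = "\n".join(rows) + "\n"
        if len(errors) >= 2 and max(errors) > min(errors):
            q = _quality.normalize_quality(errors, (min(doses), max(doses)))
            fit = _quality.fit_line(doses, q) if len(set(doses)) > 1 else None
            if fit is not None:
                report += (
                    f"# quality fit: slope={fit.slope:.4f} "
                    f"intercept={fit.intercept:.4f} r2={fit.r_squared:.4f}\n"
                )
            _quality.plot_quality_curve(
                list(zip(doses, q)), stage_dir / "quality.png", fit
            )
        (stage_dir / "report.tsv").write_text(report)
        _finish_stage(stage_dir, {"stride": config.stride})

    elif stage == "morph":
        if config.morph_seed_px is None or config.morph_interval is None:
            raise ValueError("morph stage needs morph_seed_px and morph_interval")
        for label in selected:
            vol = np.load(run_dir / "reconstruct" / f"{label}.npy")
            region = _morph.region_grow(
                vol, tuple(config.morph_seed_px), tuple(config.morph_interval)
            )
            mask = _morph.remove_small_components(
                region.mask, config.morph_min_voxels
            )
            if mask.all():
                raise ValueError("segmentation covers the whole volume")
            dist = _morph.euclidean_distance_transform(mask, config.pixel_size_um)
            hist = _morph.distance_histogram(
                dist, config.morph_bin_width_um, roi_id=label
            )
            lines = ["bin_lo_um\tbin_hi_um\tcount"]
            for lo, hi, c in zip(
                hist.bin_edges_um[:-1], hist.bin_edges_um[1:], hist.counts
            ):
                lines.append(f"{lo}\t{hi}\t{int(c)}")
            (stage_dir / f"{label}_distances.tsv").write_text("\n".join(lines) + "\n")
        _finish_stage(stage_dir, {"interval": list(config.morph_interval)})
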