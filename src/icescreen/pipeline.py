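"""End-to-end hole profiling: volume -> interfaces -> particles -> report.

``run_pipeline`` binds the analysis modules into the screening workflow
and emits a :class:`ProfileReport` that serializes to JSON.  Stages that
fail on a given volume (e.g. too few particles for a layer fit) are
recorded as indeterminate instead of aborting the whole report.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict

import numpy as np

from . import __version__
from .geometry import (
    AmbiguousInterfacesError,
    locate_interfaces,
    thickness_stats,
)
from .orientation import orientation_dispersion
from .particles import (
    adsorbed_fraction,
    assign_to_layers,
    classify_behavior,
    detect_particles,
    layer_count_token,
    projection_overlap,
)
from .volume import Volume, read_volume

__all__ = ["PipelineConfig", "ProfileReport", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Configuration of one profiling run (lengths in nm)."""

    particle_diameter: float = 12.0
    adsorption_cutoff: float = 10.0
    strategy: str = "gradient"
    layer_offset_hint: float = 5.0
    bin_factor: int = 1
    hole_radius: float | None = None  # defaults to 45% of the xy field
    orientations_csv: str | None = None  # optional per-particle axes (ground truth)
    seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


@dataclass
class ProfileReport:
    """Schema-stable result of one profiling run; all lengths nm, angles deg."""

    volume_path: str | None
    voxel_size_A: float
    volume_shape: tuple[int, int, int]
    version: str
    seed: int
    config_hash: str
    timestamp: str
    geometry: dict | None = None
    layers: list[dict] = field(default_factory=list)
    layer_token: str | None = None
    n_particles: int = 0
    adsorbed_fraction: float | None = None
    overlap_fraction: float | None = None
    uniquely_identifiable: int | None = None
    orientation: dict | None = None
    taxonomy: dict = field(default_factory=dict)
    indeterminate: dict = field(default_factory=dict)

    def to_json(self, path: str | None = None) -> str:
        d = asdict(self)
        d["units"] = {"lengths": "nm", "angles": "deg", "voxel_size": "A"}
        s = json.dumps(d, indent=1, default=_jsonable)
        if path:
            with open(path, "w") as fh:
                fh.write(s)
        return s


def _jsonable(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def run_pipeline(vol: Volume | str, config: PipelineConfig | None = None) -> ProfileReport:
    """Profile one hole volume end to end.

    Deterministic given the same volume and config; failed stages are
    recorded under ``indeterminate`` with the reason.
    """
    config = config or PipelineConfig()
    if isinstance(vol, str):
        vol = read_volume(vol)
    if config.bin_factor > 1:
        vol = vol.binned(config.bin_factor)
    nz, ny, nx = vol.shape
    vnm = vol.voxel_nm
    report = ProfileReport(
        volume_path=vol.path,
        voxel_size_A=vol.voxel_size,
        volume_shape=vol.shape,
        version=__version__,
        seed=config.seed,
        config_hash=config.config_hash(),
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    hole_radius = config.hole_radius or 0.45 * min(nx, ny) * vnm
    cx, cy = nx * vnm / 2.0, ny * vnm / 2.0
    d = config.particle_diameter

    yy, xx = np.meshgrid(vol.axis_coords_nm(1), vol.axis_coords_nm(2), indexing="ij")
    hole_mask = np.hypot(xx - cx, yy - cy) <= hole_radius
    hints = {"layer_offset": config.layer_offset_hint, "particle_diameter": d}
    try:
        bottom, top = locate_interfaces(
            vol, strategy=config.strategy, mask=hole_mask, hints=hints
        )
    except AmbiguousInterfacesError as exc:
        report.indeterminate["interfaces"] = str(exc)
        return report

    geom = thickness_stats(
        bottom,
        top,
        vol.axis_coords_nm(2),
        vol.axis_coords_nm(1),
        (cx, cy),
        hole_radius,
        particle_minor_axis=d,
    )
    report.geometry = geom.to_dict()

    dets = detect_particles(vol, diameter_range=(0.7 * d, 1.4 * d))
    if len(dets) == 0:
        report.indeterminate["particles"] = "no particles detected"
        report.layer_token = "0"
        return report
    # keep detections inside the hole and inside the ice (drop contamination,
    # rim artifacts and noise)
    centers = dets[:, :3]
    zb = bottom.evaluate(centers[:, 0], centers[:, 1])
    zt = top.evaluate(centers[:, 0], centers[:, 1])
    inside = (
        (centers[:, 2] > zb - d / 2.0)
        & (centers[:, 2] < zt + d / 2.0)
        & (np.hypot(centers[:, 0] - cx, centers[:, 1] - cy) <= hole_radius - d / 2.0)
    )
    centers = centers[inside]
    if len(centers) == 0:
        report.indeterminate["particles"] = "no detections inside the ice"
        report.layer_token = "0"
        return report

    area = np.pi * min(hole_radius, min(nx, ny) * vnm / 2.0) ** 2
    parts, layers = assign_to_layers(
        centers,
        (bottom, top),
        cutoff=config.adsorption_cutoff,
        particle_diameter=d,
        area_nm2=area,
    )
    report.n_particles = len(parts)
    report.adsorbed_fraction = float(adsorbed_fraction(parts))
    n_free = sum(1 for p in parts if not p.adsorbed)
    report.layer_token = layer_count_token(layers, n_free)
    frac, uniq = projection_overlap(np.array([p.center for p in parts]), d)
    report.overlap_fraction = frac
    report.uniquely_identifiable = uniq

    ostats = None
    if config.orientations_csv:
        vecs = np.loadtxt(config.orientations_csv, delimiter=",", skiprows=1,
                          usecols=(3, 4, 5))
        ostats = orientation_dispersion(vecs)
        report.orientation = {
            "n": ostats.n,
            "resultant_length": ostats.resultant_length,
            "mode_count": ostats.mode_count,
            "dispersion_class": ostats.dispersion_class,
        }
    for layer in layers:
        layer.behavior = classify_behavior(layer, ostats)
    report.layers = [asdict(l) for l in layers]
    report.taxonomy = {
        "C_bottom": geom.curvature_bottom,
        "C_top": geom.curvature_top,
        "B": sorted({l.behavior for l in layers} | ({"B1"} if n_free else set())),
    }
    return report
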