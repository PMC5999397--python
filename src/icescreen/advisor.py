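"""Collection-strategy recommendation from a measured characterization.

Once a hole has been profiled (ice geometry, particle layers, orientation
statistics), a screening session ends with a practical decision.  The rule
cascade mirrors how such data is read in practice:

1. If the ice thins toward the hole centre until only a single particle
   layer fits (particle minor axis plus ~20 nm of clearance), collect a
   distance ``d`` in from the hole edge where that band starts — on real
   holes typically 100-500 nm from the edge.
2. Otherwise, a single layer with strong preferred orientation calls for
   tilted collection with a small set of stage tilts chosen to maximize
   angular coverage.
3. Otherwise (double layers or thick ice everywhere) collection can
   proceed with caveats — the bilayer midway-defocus resolution limit is
   attached — or the grid is rejected outright when the ice exceeds
   ~100 nm everywhere and the layers are sparsely saturated.

Every recommendation lists the rules that fired, so the decision is
auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import ctf
from .geometry import IceGeometry
from .orientation import OrientationStats, tilt_expanded_coverage
from .particles import LayerModel

__all__ = ["Recommendation", "recommend_strategy"]

#: clearance above the particle minor axis that still admits only one layer
SINGLE_LAYER_CLEARANCE_NM = 20.0
#: near-ideal ice thickness ceiling
THICK_ICE_NM = 100.0
#: layers below this saturation make thick-ice collection not worth the dose
LOW_SATURATION_PCT = 30.0

_ACTION_ORDER = ["collect_at_offset", "tilted_collection", "collect_with_caveats", "reject"]


@dataclass
class Recommendation:
    action: str  # collect_at_offset | tilted_collection | collect_with_caveats | reject
    rationale: list[str]
    offset_d: float | None = None  # nm in from the hole edge
    tilt_angles: list[float] = field(default_factory=list)
    expected_limits: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.action not in _ACTION_ORDER and self.action != "indeterminate":
            raise ValueError(f"unknown action {self.action!r}")
        if self.action == "collect_at_offset" and not (
            self.offset_d is not None and self.offset_d > 0
        ):
            raise ValueError("collect_at_offset requires a positive offset_d")
        if not self.rationale:
            raise ValueError("rationale must not be empty")


def _radial_thickness_profile(geom: IceGeometry, n_bins: int = 64):
    """Mean thickness vs radius from the thickness map."""
    tmap = geom.thickness_map
    ny, nx = tmap.shape
    # the map is stored on a grid spanning the analysed field; reconstruct radii
    yy, xx = np.mgrid[0:ny, 0:nx]
    valid = np.isfinite(tmap)
    if not valid.any():
        return None, None
    # grid spacing from hole radius: the mask extends to r = hole_radius
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    r_pix = np.hypot(xx - cx, yy - cy)
    scale = geom.hole_radius / r_pix[valid].max()
    r_nm = r_pix * scale
    bins = np.linspace(0, geom.hole_radius, n_bins + 1)
    idx = np.digitize(r_nm[valid], bins) - 1
    prof = np.full(n_bins, np.nan)
    tv = tmap[valid]
    for i in range(n_bins):
        sel = idx == i
        if sel.any():
            prof[i] = tv[sel].mean()
    centers = 0.5 * (bins[:-1] + bins[1:])
    return centers, prof


def recommend_strategy(
    geometry: IceGeometry | None,
    layers: list[LayerModel] | None,
    orientation: OrientationStats | None,
    particle_diameter: float,
    single_layer_clearance: float = SINGLE_LAYER_CLEARANCE_NM,
    thick_ice: float = THICK_ICE_NM,
    params: ctf.CtfParams | None = None,
) -> Recommendation:
    """Apply the rule cascade to one hole characterization.

    Incomplete input yields an ``indeterminate`` recommendation naming the
    missing pieces; otherwise exactly one action results.
    """
    missing = [
        name
        for name, val in (
            ("geometry", geometry),
            ("layers", layers),
            ("orientation", orientation),
        )
        if val is None
    ]
    if missing:
        return Recommendation(
            action="indeterminate",
            rationale=[f"incomplete characterization, missing: {', '.join(missing)}"],
        )

    rationale: list[str] = []
    single_ceiling = particle_diameter + single_layer_clearance

    # rule 1: a radial band thin enough for exactly one layer
    radii, prof = _radial_thickness_profile(geometry)
    if radii is not None:
        fits_one = (prof >= particle_diameter) & (prof <= single_ceiling)
        if np.any(np.nan_to_num(fits_one)):
            r_outer = float(radii[np.where(fits_one)[0].max()])
            d = geometry.hole_radius - r_outer
            rationale.append(
                f"ice thins to <= {single_ceiling:.0f} nm (particle {particle_diameter:.0f} nm "
                f"+ {single_layer_clearance:.0f} nm clearance) starting {d:.0f} nm from the edge"
            )
            return Recommendation(
                action="collect_at_offset", rationale=rationale, offset_d=max(d, 1.0)
            )

    n_layers = sum(1 for l in layers if l.count >= 3)
    # rule 2: single layer but strong preferred orientation
    if n_layers <= 1 and orientation.dispersion_class == "strong":
        tilts = _choose_tilts(orientation)
        rationale.append(
            "single particle layer with strong preferred orientation; "
            f"stage tilts {tilts} maximize angular coverage"
        )
        return Recommendation(
            action="tilted_collection", rationale=rationale, tilt_angles=tilts
        )
    if n_layers <= 1:
        rationale.append("single layer without a thin-band offset; collectible as-is")
        return Recommendation(action="collect_with_caveats", rationale=rationale)

    # rule 3: double layers / thick ice
    t_min = float(np.nanmin(geometry.thickness_map))
    max_sat = max((l.saturation for l in layers), default=0.0)
    limit = ctf.defocus_error_resolution_limit(
        ctf.bilayer_defocus_offset(t_min) * 10.0, params  # nm -> A
    )
    limits = {"bilayer_midway_limit_A": limit}
    if t_min > thick_ice and max_sat < LOW_SATURATION_PCT:
        rationale.append(
            f"ice > {thick_ice:.0f} nm everywhere with sparse layers "
            f"(max saturation {max_sat:.0f}%); not worth collecting"
        )
        return Recommendation(action="reject", rationale=rationale, expected_limits=limits)
    rationale.append(
        f"two particle layers; midway defocus estimation limits resolution to "
        f"~{limit if isinstance(limit, str) else round(limit, 1)} A unless "
        "per-particle defocus or duplicate-defocus rescue is used"
    )
    return Recommendation(
        action="collect_with_caveats", rationale=rationale, expected_limits=limits
    )


def _choose_tilts(orientation: OrientationStats, candidates=(15.0, 30.0, 45.0)) -> list[float]:
    """Greedy 2-tilt choice maximizing tilt-expanded coverage."""
    modes = orientation.modes or [(0.0, 0.0, 1.0)]
    best: tuple[float, list[float]] = (-1.0, [0.0])
    for t1 in candidates:
        for tilts in ([0.0, t1],):
            cov = tilt_expanded_coverage(modes, tilts=tilts, bandwidth=10.0, n_grid=2000)
            if cov > best[0]:
                best = (cov, tilts)
    return best[1]
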