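"""Particle detection, layer assignment and adsorption statistics.

The survey's headline observation is that most particles in grid holes sit
within 5-10 nm of an air-water interface.  This module detects particle
centroids in a volume (multi-scale Laplacian-of-Gaussian blob detection),
measures each centroid's signed distance to the two interfaces, groups the
close ones into bottom/top layers, and computes the derived statistics:
adsorbed fraction, per-layer saturation and tilt, the projection-overlap
count that limits usable particles in untilted micrographs, and the B1-B5
behavior code of each layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .geometry import InterfaceSurface, fit_surface, surface_tilt
from .phantom import HEX_PACKING_LIMIT
from .volume import Volume

__all__ = [
    "Particle",
    "LayerModel",
    "detect_particles",
    "assign_to_layers",
    "adsorbed_fraction",
    "layer_tilt",
    "layer_saturation",
    "projection_overlap",
    "classify_behavior",
    "layer_count_token",
]

#: default adsorption cutoff; the survey reports layers 5-10 nm from interfaces
ADSORPTION_CUTOFF_NM = 10.0


@dataclass
class Particle:
    """One detected (or ground-truth) particle with interface distances."""

    center: tuple[float, float, float]  # x, y, z nm
    diameter: float
    d_bottom: float  # signed nm, positive = inside the ice
    d_top: float
    adsorbed: bool
    side: str  # bottom | top | none
    layer_id: int | None
    orientation: tuple[float, float, float] | None = None
    score: float = 0.0


@dataclass
class LayerModel:
    """An interface-adsorbed particle layer."""

    layer_id: int
    side: str
    mean_offset: float  # nm from the interface
    tilt: float  # degrees from the beam axis
    count: int
    saturation: float  # % of hexagonal packing
    behavior: str = "unknown"  # B1..B5 | unknown

    def __post_init__(self) -> None:
        if not (0.0 <= self.saturation <= 100.0):
            raise ValueError("saturation must be within 0-100%")
        if not (0.0 <= self.tilt < 90.0):
            raise ValueError("tilt must be in [0, 90)")


def detect_particles(
    vol: Volume,
    diameter_range: tuple[float, float],
    n_scales: int = 3,
    threshold: float | None = None,
    threshold_sigmas: float = 10.0,
) -> np.ndarray:
    """Multi-scale LoG blob detection of dark (dense) particles.

    Returns an (n, 5) array of ``x_nm, y_nm, z_nm, diameter_nm, score``
    sorted by decreasing score.  The detection threshold adapts to the
    response noise (median + ``threshold_sigmas`` * MAD-sigma) unless an
    absolute ``threshold`` is given; no two detections lie closer than
    0.7 x diameter.  An empty result is valid.
    """
    dmin, dmax = diameter_range
    if not (2.0 <= dmin <= dmax <= 60.0):
        raise ValueError("diameter_range must lie within 2-60 nm")
    vnm = vol.voxel_nm
    if dmin < 4.0 * vnm:
        raise ValueError(
            f"diameter {dmin} nm is below Nyquist for {vnm} nm voxels"
        )
    inv = -vol.data.astype(np.float32)  # particles become bright
    # blob radius r maps to LoG scale sigma = r / sqrt(3)
    sigmas_nm = np.geomspace(dmin / 2.0, dmax / 2.0, n_scales) / math.sqrt(3.0)
    best = np.full(vol.shape, -np.inf, dtype=np.float32)
    best_s = np.zeros(vol.shape, dtype=np.float32)
    for s_nm in sigmas_nm:
        s_vox = s_nm / vnm
        resp = -(s_vox**2) * ndimage.gaussian_laplace(inv, s_vox)
        upd = resp > best
        best[upd] = resp[upd]
        best_s[upd] = s_nm
    if threshold is None:
        med = float(np.median(best))
        mad = float(np.median(np.abs(best - med)))
        threshold = max(med + threshold_sigmas * 1.4826 * mad, 0.02)
    min_dist_vox = max(1, int(round(0.7 * 0.5 * (dmin + dmax) / vnm)))
    footprint = np.ones((3, 3, 3), dtype=bool)
    local_max = best == ndimage.maximum_filter(best, footprint=footprint)
    cand = np.argwhere(local_max & (best > threshold))
    if cand.size == 0:
        return np.empty((0, 5))
    # interface steps also excite the LoG; a genuine blob is darker than its
    # surroundings in (almost) every axis direction at one radius out
    smoothed = ndimage.gaussian_filter(vol.data, max(1.0, 0.1 * dmin / vnm))
    keep_blob = np.ones(len(cand), dtype=bool)
    nzyx = np.array(vol.shape)
    probe_vox = max(2, int(round(0.6 * dmax / vnm)))
    for idx, c in enumerate(cand):
        r_vox = probe_vox
        dz = []
        for sgn in (-1, 1):
            p = c.copy()
            p[0] = np.clip(p[0] + sgn * r_vox, 0, nzyx[0] - 1)
            dz.append(smoothed[tuple(p)] - smoothed[tuple(c)])
        # a blob is darker than both its z neighbours; a (near-horizontal)
        # interface step is antisymmetric along z so the sum cancels
        if not (dz[0] + dz[1] > 0.1):
            keep_blob[idx] = False
    cand = cand[keep_blob]
    if cand.size == 0:
        return np.empty((0, 5))
    scores = best[tuple(cand.T)]
    order = np.argsort(scores)[::-1]
    cand, scores = cand[order], scores[order]
    kept: list[int] = []
    for i, c in enumerate(cand):
        ok = True
        for j in kept:
            if np.sum((cand[j] - c) ** 2) < min_dist_vox**2:
                ok = False
                break
        if ok:
            kept.append(i)
    # recenter each detection on the local response centre of mass; for
    # elongated particles the maximum wanders along the response ridge
    nz, ny, nx = vol.shape
    wr = max(2, int(round(0.7 * 0.5 * (dmin + dmax) / vnm)))
    zz, yy, xx = np.mgrid[-wr : wr + 1, -wr : wr + 1, -wr : wr + 1]
    ball = (zz**2 + yy**2 + xx**2) <= wr**2
    out = []
    for i in kept:
        zi, yi, xi = (float(v) for v in cand[i])
        for _ in range(2):  # recentre twice: the window follows the estimate
            z0, y0, x0 = (int(round(v)) - wr for v in (zi, yi, xi))
            z1, y1, x1 = z0 + 2 * wr + 1, y0 + 2 * wr + 1, x0 + 2 * wr + 1
            if min(z0, y0, x0) < 0 or z1 > nz or y1 > ny or x1 > nx:
                break
            w = np.clip(best[z0:z1, y0:y1, x0:x1] - threshold, 0.0, None) * ball
            tot = w.sum()
            if tot <= 0:
                break
            zi = z0 + float((w.sum(axis=(1, 2)) * np.arange(2 * wr + 1)).sum() / tot)
            yi = y0 + float((w.sum(axis=(0, 2)) * np.arange(2 * wr + 1)).sum() / tot)
            xi = x0 + float((w.sum(axis=(0, 1)) * np.arange(2 * wr + 1)).sum() / tot)
        out.append(
            [
                (xi + 0.5) * vnm,
                (yi + 0.5) * vnm,
                (zi + 0.5) * vnm,
                2.0 * math.sqrt(3.0) * best_s[tuple(cand[i])],
                float(scores[i]),
            ]
        )
    return np.array(out)


def assign_to_layers(
    centroids: np.ndarray,
    surfaces: tuple[InterfaceSurface, InterfaceSurface],
    cutoff: float = ADSORPTION_CUTOFF_NM,
    particle_diameter: float = 10.0,
    area_nm2: float | None = None,
    distance_mode: str = "z",
) -> tuple[list[Particle], list[LayerModel]]:
    """Assign centroids to interface layers.

    Distances are measured from the particle centre to each surface along z
    (``distance_mode="z"``, the slice-based convention) or along the surface
    normal (``"normal"``).  A particle within ``cutoff`` of a surface joins
    that side's layer; the rest are non-adsorbed (B1 candidates).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    bottom, top = surfaces
    pts = np.asarray(centroids, dtype=float).reshape(-1, 3)
    cx, cy = bottom.center_xy
    if bottom.evaluate(cx, cy) >= top.evaluate(cx, cy):
        raise ValueError("surfaces cross: bottom is not below top")
    particles: list[Particle] = []
    for x, y, z in pts:
        db = z - float(bottom.evaluate(x, y))
        dt = float(top.evaluate(x, y)) - z
        if distance_mode == "normal":
            db /= math.sqrt(1.0 + bottom.a**2 + bottom.b**2)
            dt /= math.sqrt(1.0 + top.a**2 + top.b**2)
        if db <= dt:
            side, dmin = "bottom", db
        else:
            side, dmin = "top", dt
        adsorbed = dmin <= cutoff
        particles.append(
            Particle(
                center=(float(x), float(y), float(z)),
                diameter=particle_diameter,
                d_bottom=float(db),
                d_top=float(dt),
                adsorbed=adsorbed,
                side=side if adsorbed else "none",
                layer_id=(0 if side == "bottom" else 1) if adsorbed else None,
            )
        )
    layers: list[LayerModel] = []
    for lid, side in ((0, "bottom"), (1, "top")):
        members = [p for p in particles if p.layer_id == lid]
        if not members:
            continue
        offs = [p.d_bottom if side == "bottom" else p.d_top for p in members]
        if len(members) >= 3:
            try:
                tilt = layer_tilt(np.array([p.center for p in members]))
            except ValueError:
                tilt = surface_tilt(bottom if side == "bottom" else top)
        else:
            tilt = surface_tilt(bottom if side == "bottom" else top)
        sat = (
            layer_saturation(len(members), particle_diameter, area_nm2)
            if area_nm2
            else 0.0
        )
        layers.append(
            LayerModel(
                layer_id=lid,
                side=side,
                mean_offset=float(np.mean(offs)),
                tilt=tilt,
                count=len(members),
                saturation=sat,
            )
        )
    return particles, layers


def adsorbed_fraction(particles: list[Particle]) -> Fraction:
    """Exact fraction of particles adsorbed to an interface."""
    if not particles:
        raise ValueError("empty particle list")
    return Fraction(sum(p.adsorbed for p in particles), len(particles))


def layer_tilt(points: np.ndarray) -> float:
    """Tilt (degrees) of the plane fitted through layer particle centres.

    One trimmed refit pass rejects stray centroids (spurious detections or
    particles straddling the cutoff) before the angle is taken.
    """
    plane = fit_surface(np.asarray(points, dtype=float), order=1, trim_sigma=2.5)
    return surface_tilt(plane)


def layer_saturation(count: int, particle_diameter: float, area_nm2: float) -> float:
    """Saturation % of a layer: occupied footprint over hexagonal packing.

    100% means no additional particles could be fit into the layer.
    """
    if area_nm2 <= 0:
        raise ValueError("area must be positive")
    if count < 0:
        raise ValueError("count must be >= 0")
    foot = math.pi * (particle_diameter / 2.0) ** 2
    return min(100.0, 100.0 * count * foot / (area_nm2 * HEX_PACKING_LIMIT))


def projection_overlap(
    centers: np.ndarray, diameter: float
) -> tuple[float, int]:
    """Overlap statistics of particles projected along the beam.

    A particle overlaps when any other centre lies within one diameter in
    (x, y); the rest would be uniquely identifiable in the projection
    image.  Returns ``(overlap_fraction, uniquely_identifiable_count)``.
    """
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    pts = np.asarray(centers, dtype=float).reshape(-1, 3)[:, :2]
    n = len(pts)
    if n == 0:
        return 0.0, 0
    tree = cKDTree(pts)
    pairs = tree.query_pairs(r=diameter, output_type="ndarray")
    overlapping = np.zeros(n, dtype=bool)
    if len(pairs):
        overlapping[pairs.ravel()] = True
    n_over = int(overlapping.sum())
    return n_over / n, n - n_over


def classify_behavior(
    layer: LayerModel | None,
    orientation_stats=None,
    fragments_annotation: bool | None = None,
) -> str:
    """Map a layer plus orientation statistics to a B1-B5 behavior code.

    B1 non-adsorbed; B2 adsorbed without preferred orientation; B3 adsorbed
    with preferred orientation modes.  B4/B5 (denaturation) are only
    assignable from ground-truth or manual fragment annotation — automated
    denaturation detection is not attempted — otherwise ``unknown``.
    """
    if layer is None or layer.side == "none":
        return "B1"
    if fragments_annotation:
        return "B4"
    if orientation_stats is None:
        return "unknown"
    if layer.count < 5:
        return "unknown"
    # preferred orientation: concentrated modes hold most of the mass, or a
    # single dominant direction (strong resultant); antipodal bimodality has
    # R ~ 0 but is still preferred orientation
    modal = (
        orientation_stats.mode_count >= 1
        and orientation_stats.mode_mass >= 0.8
    )
    if modal or orientation_stats.dispersion_class == "strong":
        return "B3"
    return "B2"


def layer_count_token(
    layers: list[LayerModel],
    n_free: int,
    min_count: int = 3,
    sub_region_tokens: list[str] | None = None,
) -> str:
    """Layer-count vocabulary of the survey tables.

    ``0``/``1``/``2`` count the populated layers; ``1-2`` is emitted when
    different sub-regions of one field disagree; a trailing ``+`` marks
    extra non-adsorbed particles (more than 5% of the layered count).
    """
    n_layers = sum(1 for l in layers if l.count >= min_count)
    token = str(n_layers)
    if sub_region_tokens:
        uniq = sorted(set(sub_region_tokens) | {token})
        if len(uniq) > 1:
            token = f"{uniq[0]}-{uniq[-1]}"
    layered = sum(l.count for l in layers)
    if layered and n_free > 0.05 * layered:
        token += "+"
    return token
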