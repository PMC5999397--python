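"""Synthetic grid-hole tomogram phantoms with known ground truth.

The generator emulates what a tomogram of a single-particle cryoEM grid
hole shows: a slab of vitreous ice bounded by two air-water interfaces
with configurable curvature (C1-C4) and tilt, particle layers adsorbed at
a small offset from the interfaces, non-adsorbed particles in the bulk,
surface ice contamination, small protein-fragment debris, Gaussian noise
and an optional missing-wedge filter.  Every stochastic choice flows from
one seed, so identical (config, seed) gives bit-identical volumes, and a
:class:`GroundTruth` sidecar records everything the downstream analysis
is later asked to recover.

Density convention: denser material is darker (lower values), matching
cryoEM contrast.  Air is 0, vitreous ice ``ICE_DELTA`` below air, and
particles/contamination darker still; the constants are module-level and
arbitrary since only contrast ratios matter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .geometry import InterfaceSurface
from .volume import Volume

__all__ = [
    "SurfaceProfile",
    "PhantomConfig",
    "GroundTruth",
    "TruthParticle",
    "InfeasibleConfigError",
    "make_phantom",
    "ground_truth_surfaces",
    "sample_orientations",
    "write_ground_truth",
    "read_ground_truth",
]

# density offsets (arbitrary units); darker = denser
AIR_LEVEL = 0.0
ICE_DELTA = -0.3
PARTICLE_DELTA = -0.7  # added on top of the ice level
CONTAMINATION_DELTA = -0.9
FRAGMENT_DELTA = -0.5

#: hexagonal close-packing area fraction; 100% layer saturation reference
HEX_PACKING_LIMIT = 0.9069

CURVATURE_CLASSES = ("C1", "C2", "C3", "C4")


class InfeasibleConfigError(ValueError):
    """A phantom configuration violates a packing or geometry bound."""


@dataclass
class SurfaceProfile:
    """Radial profile of one interface: distance (nm) from the ice midplane.

    ``center_offset`` applies at the hole centre, ``edge_offset`` at the
    rim; between them the offset varies quadratically with radius.  The
    curvature class must be consistent with the offsets (C1 bulges outward
    so the ice is thicker at the centre; C3/C4 the opposite; C2 flat).
    """

    curvature: str = "C2"
    center_offset: float = 15.0
    edge_offset: float = 15.0

    def __post_init__(self) -> None:
        if self.curvature not in CURVATURE_CLASSES:
            raise ValueError(f"curvature must be one of {CURVATURE_CLASSES}")
        d = self.center_offset - self.edge_offset
        if self.curvature == "C1" and d <= 0:
            raise ValueError("C1 requires center_offset > edge_offset")
        if self.curvature == "C2" and abs(d) > 1e-9:
            raise ValueError("C2 requires equal center and edge offsets")
        if self.curvature in ("C3", "C4") and d >= 0:
            raise ValueError(f"{self.curvature} requires center_offset < edge_offset")


@dataclass
class PhantomConfig:
    """Full generative description of one synthetic grid-hole volume.

    Lengths are nm except ``voxel_size`` (Å).  Defaults follow the typical
    survey conditions: a thin-centre/thicker-edge hole (concave C3 on both
    sides), ~5 degree interface tilt, 90% of particles adsorbed in layers
    5 nm from an interface, and noise giving particle contrast SNR ~ 3.
    """

    volume_shape: tuple[int, int, int] = (256, 256, 256)  # (nz, ny, nx) voxels
    voxel_size: float = 8.0  # A per voxel (tomogram binned by 4 at 2 A/px)
    hole_radius: float = 90.0
    bottom_profile: SurfaceProfile = field(
        default_factory=lambda: SurfaceProfile("C3", 15.0, 35.0)
    )
    top_profile: SurfaceProfile = field(
        default_factory=lambda: SurfaceProfile("C3", 15.0, 35.0)
    )
    interface_tilt: float = 5.0  # degrees, rigid plane tilt of both surfaces
    tilt_azimuth: float = 0.0  # degrees in the xy plane; 0 = slope along x
    particle_diameter: float = 12.0  # nm, minor axis
    particle_aspect: float = 1.6  # long axis / minor axis of the ellipsoid
    n_particles: int = 150
    adsorbed_fraction: float = 0.9
    layer_offset: float = 5.0  # nm from interface to adsorbed particle centre
    layer_split: float = 0.5  # fraction of adsorbed particles on the bottom
    orientation_model: object = "uniform"  # or [(direction, kappa), ...]
    saturation_cap: float = 100.0  # % of hexagonal packing per layer
    n_free_particles: int = 0  # extra non-adsorbed particles mid-ice
    contamination_density: float = 0.0  # blobs per um^2 per surface
    fragment_density: float = 0.0  # debris blobs per um^2 per interface
    noise_sigma: float = 0.0  # density units
    missing_wedge: bool = False
    retained_tilt: float = 45.0  # degrees, +/- range kept when wedge is on
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.adsorbed_fraction <= 1.0):
            raise ValueError("adsorbed_fraction must be in [0, 1]")
        if not (0.0 <= self.layer_split <= 1.0):
            raise ValueError("layer_split must be in [0, 1]")
        if not (0.0 <= self.layer_offset <= 10.0):
            raise ValueError("layer_offset must be within 0-10 nm")
        if self.particle_diameter <= 0:
            raise ValueError("particle_diameter must be positive")
        fov_xy = min(self.volume_shape[1], self.volume_shape[2]) * self.voxel_size / 10.0
        if self.hole_radius > fov_xy:
            raise ValueError("hole_radius must fit in the field of view")
        t_center = self.bottom_profile.center_offset + self.top_profile.center_offset
        t_max = max(
            t_center,
            self.bottom_profile.edge_offset + self.top_profile.edge_offset,
        )
        z_extent = self.volume_shape[0] * self.voxel_size / 10.0
        if z_extent < 1.2 * t_max:
            raise ValueError(
                f"volume z extent {z_extent:.0f} nm must cover max ice "
                f"thickness {t_max:.0f} nm plus a 20% margin"
            )
        c4 = "C4" in (self.bottom_profile.curvature, self.top_profile.curvature)
        if c4 and t_center >= self.particle_diameter:
            raise ValueError(
                "C4 requires centre thickness below the particle minor axis"
            )

    @property
    def z_mid(self) -> float:
        return self.volume_shape[0] * self.voxel_size / 20.0

    def thickness_center(self) -> float:
        return self.bottom_profile.center_offset + self.top_profile.center_offset

    def thickness_edge(self) -> float:
        return self.bottom_profile.edge_offset + self.top_profile.edge_offset


@dataclass
class TruthParticle:
    center: tuple[float, float, float]  # x, y, z nm
    orientation: tuple[float, float, float]  # unit vector, long axis
    adsorbed: bool
    side: str  # bottom | top | none
    layer_id: int | None


@dataclass
class GroundTruth:
    """Everything the generator knows about one phantom."""

    particles: list[TruthParticle]
    surfaces: dict  # analytic surface parameters per side
    thickness_center: float
    thickness_edge: float
    taxonomy: dict  # A/B/C codes realized by the configuration
    realized_adsorbed_fraction: float
    saturation: dict  # % per layer side
    seed: int
    config: dict  # the generating PhantomConfig as a plain dict

    def adsorbed_count(self) -> int:
        return sum(p.adsorbed for p in self.particles)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        parts = [
            TruthParticle(
                tuple(p["center"]),
                tuple(p["orientation"]),
                bool(p["adsorbed"]),
                p["side"],
                p["layer_id"],
            )
            for p in d["particles"]
        ]
        return cls(
            particles=parts,
            surfaces=d["surfaces"],
            thickness_center=d["thickness_center"],
            thickness_edge=d["thickness_edge"],
            taxonomy=d["taxonomy"],
            realized_adsorbed_fraction=d["realized_adsorbed_fraction"],
            saturation=d["saturation"],
            seed=d["seed"],
            config=d["config"],
        )


def ground_truth_surfaces(config: PhantomConfig) -> tuple[InterfaceSurface, InterfaceSurface]:
    """Analytic bottom/top interfaces implied by a config (no rendering).

    The radial quadratic profile maps exactly onto the surface model used
    by the geometry module; the rigid tilt contributes the plane slope, so
    the analytic tilt equals ``config.interface_tilt`` by construction.
    """
    nz, ny, nx = config.volume_shape
    vnm = config.voxel_size / 10.0
    cx, cy = nx * vnm / 2.0, ny * vnm / 2.0
    slope = np.tan(np.radians(config.interface_tilt))
    az = np.radians(config.tilt_azimuth)
    ax, ay = slope * np.cos(az), slope * np.sin(az)
    R = config.hole_radius

    def _surf(profile: SurfaceProfile, sign: float, side: str) -> InterfaceSurface:
        oc, oe = profile.center_offset, profile.edge_offset
        quad = sign * (oe - oc) / R**2
        c = config.z_mid + sign * oc - ax * cx - ay * cy
        return InterfaceSurface(
            side=side, a=ax, b=ay, c=c, quad=quad, center_xy=(cx, cy),
            r_max=R, locator="analytic",
        )

    return (_surf(config.bottom_profile, -1.0, "bottom"),
            _surf(config.top_profile, +1.0, "top"))


def sample_orientations(model, n: int, seed=0) -> np.ndarray:
    """Sample *n* unit vectors from an orientation model.

    ``model`` is ``"uniform"`` or a list of ``(direction, kappa)`` von
    Mises-Fisher modes (equal weights); ``seed`` may be an int or a
    ``numpy.random.Generator``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if isinstance(model, str):
        if model != "uniform":
            raise ValueError(f"unknown orientation model {model!r}")
        v = rng.normal(size=(n, 3))
        return v / np.linalg.norm(v, axis=1, keepdims=True)
    modes = list(model)
    if not modes:
        raise ValueError("non-uniform orientation model needs at least one mode")
    dirs = []
    kappas = []
    for mu, kappa in modes:
        mu = np.asarray(mu, dtype=float)
        nrm = np.linalg.norm(mu)
        if nrm == 0:
            raise ValueError("mode direction must be nonzero")
        if kappa < 0:
            raise ValueError("concentrations must be >= 0")
        dirs.append(mu / nrm)
        kappas.append(float(kappa))
    which = rng.integers(0, len(dirs), size=n)
    out = np.empty((n, 3))
    for i, k in enumerate(which):
        out[i] = _sample_vmf(dirs[k], kappas[k], rng)
    return out


def _sample_vmf(mu: np.ndarray, kappa: float, rng: np.random.Generator) -> np.ndarray:
    """One von Mises-Fisher draw on S^2 (inversion method for the colatitude)."""
    if kappa == 0:
        v = rng.normal(size=3)
        return v / np.linalg.norm(v)
    u = rng.uniform()
    # w = cos(theta) about the mode; closed-form inverse CDF on S^2
    w = 1.0 + np.log(u + (1.0 - u) * np.exp(-2.0 * kappa)) / kappa
    phi = rng.uniform(0.0, 2.0 * np.pi)
    s = np.sqrt(max(0.0, 1.0 - w * w))
    local = np.array([s * np.cos(phi), s * np.sin(phi), w])
    # rotate the pole onto mu
    z = np.array([0.0, 0.0, 1.0])
    if np.allclose(mu, z):
        return local
    if np.allclose(mu, -z):
        return -local
    axis = np.cross(z, mu)
    axis /= np.linalg.norm(axis)
    ang = np.arccos(np.clip(mu @ z, -1.0, 1.0))
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    Rm = np.eye(3) + np.sin(ang) * K + (1 - np.cos(ang)) * (K @ K)
    v = Rm @ local
    return v / np.linalg.norm(v)


def _poisson_disc(
    rng: np.random.Generator,
    n: int,
    r_place: float,
    center: tuple[float, float],
    spacing: float,
    accept,
    max_tries: int = 200,
) -> np.ndarray:
    """Dart-throwing placement of *n* points with a minimum spacing.

    ``accept(x, y)`` may veto positions (e.g. C4-thin regions).  Raises
    :class:`InfeasibleConfigError` when the request cannot be packed.
    """
    pts: list[tuple[float, float]] = []
    tries = 0
    budget = max_tries * max(n, 1)
    cx, cy = center
    while len(pts) < n:
        if tries >= budget:
            raise InfeasibleConfigError(
                f"could not place {n} particles with spacing {spacing:.1f} nm "
                f"in a disc of radius {r_place:.0f} nm (packing bound exceeded "
                f"after {tries} attempts)"
            )
        tries += 1
        rr = r_place * np.sqrt(rng.uniform())
        th = rng.uniform(0, 2 * np.pi)
        x, y = cx + rr * np.cos(th), cy + rr * np.sin(th)
        if not accept(x, y):
            continue
        ok = all((x - px) ** 2 + (y - py) ** 2 >= spacing**2 for px, py in pts)
        if ok:
            pts.append((x, y))
    return np.array(pts).reshape(n, 2)


def _render_ellipsoids(
    data: np.ndarray,
    centers: np.ndarray,
    orients: np.ndarray,
    minor: float,
    aspect: float,
    vnm: float,
    delta: float,
    edge_nm: float = 0.8,
) -> None:
    """Add soft-edged ellipsoids (long axis along the orientation) in place."""
    from scipy.special import erfc

    nz, ny, nx = data.shape
    b = minor / 2.0
    a = aspect * b
    pad = a + 3.0 * edge_nm
    for (x, y, z), v in zip(centers, orients):
        i0 = max(int((z - pad) / vnm), 0)
        i1 = min(int((z + pad) / vnm) + 2, nz)
        j0 = max(int((y - pad) / vnm), 0)
        j1 = min(int((y + pad) / vnm) + 2, ny)
        k0 = max(int((x - pad) / vnm), 0)
        k1 = min(int((x + pad) / vnm) + 2, nx)
        if i0 >= i1 or j0 >= j1 or k0 >= k1:
            continue
        zz = (np.arange(i0, i1) + 0.5) * vnm - z
        yy = (np.arange(j0, j1) + 0.5) * vnm - y
        xx = (np.arange(k0, k1) + 0.5) * vnm - x
        Z, Y, X = np.meshgrid(zz, yy, xx, indexing="ij")
        # component along the long axis (orientation v is (vx, vy, vz))
        par = X * v[0] + Y * v[1] + Z * v[2]
        perp2 = X * X + Y * Y + Z * Z - par * par
        q = np.sqrt((par / a) ** 2 + np.clip(perp2, 0, None) / b**2)
        # signed distance from the surface, approximated with the minor radius
        f = 0.5 * erfc((q - 1.0) * b / edge_nm)
        data[i0:i1, j0:j1, k0:k1] += delta * f.astype(np.float32)


def _render_spheres(
    data: np.ndarray,
    centers: np.ndarray,
    radii: np.ndarray,
    vnm: float,
    delta: float,
    edge_nm: float = 0.8,
) -> None:
    from scipy.special import erfc

    nz, ny, nx = data.shape
    for (x, y, z), r in zip(centers, radii):
        pad = r + 3.0 * edge_nm
        i0, i1 = max(int((z - pad) / vnm), 0), min(int((z + pad) / vnm) + 2, nz)
        j0, j1 = max(int((y - pad) / vnm), 0), min(int((y + pad) / vnm) + 2, ny)
        k0, k1 = max(int((x - pad) / vnm), 0), min(int((x + pad) / vnm) + 2, nx)
        if i0 >= i1 or j0 >= j1 or k0 >= k1:
            continue
        zz = (np.arange(i0, i1) + 0.5) * vnm - z
        yy = (np.arange(j0, j1) + 0.5) * vnm - y
        xx = (np.arange(k0, k1) + 0.5) * vnm - x
        Z, Y, X = np.meshgrid(zz, yy, xx, indexing="ij")
        d = np.sqrt(X * X + Y * Y + Z * Z)
        f = 0.5 * erfc((d - r) / edge_nm)
        data[i0:i1, j0:j1, k0:k1] += delta * f.astype(np.float32)


def _apply_missing_wedge(data: np.ndarray, retained_tilt: float) -> np.ndarray:
    """Zero Fourier coefficients outside the retained tilt range.

    The tilt axis is x, so the wedge lives in the (kz, ky) plane: a
    direction is sampled when its angle from the ky axis is within the
    retained range, i.e. atan2(|kz|, |ky|) <= retained_tilt.
    """
    nz, ny, nx = data.shape
    F = np.fft.rfftn(data)
    kz = np.fft.fftfreq(nz)[:, None]
    ky = np.fft.fftfreq(ny)[None, :]
    ang = np.degrees(np.arctan2(np.abs(kz), np.abs(ky)))
    keep = (ang <= retained_tilt) | ((kz == 0) & (ky == 0))
    F *= keep[:, :, None]
    return np.fft.irfftn(F, s=data.shape, axes=(0, 1, 2)).astype(np.float32)


def layer_saturation_percent(count: int, particle_diameter: float, area_nm2: float) -> float:
    """Layer saturation in %, relative to hexagonal close packing."""
    if area_nm2 <= 0:
        raise ValueError("area must be positive")
    foot = np.pi * (particle_diameter / 2.0) ** 2
    return min(100.0, 100.0 * count * foot / (area_nm2 * HEX_PACKING_LIMIT))


def make_phantom(config: PhantomConfig) -> tuple[Volume, GroundTruth]:
    """Generate a synthetic hole volume and its ground truth.

    Raises :class:`InfeasibleConfigError` when the requested particle count
    cannot be packed under ``saturation_cap`` or the layer geometry.
    """
    nz, ny, nx = config.volume_shape
    vnm = config.voxel_size / 10.0
    rng = np.random.default_rng(config.seed)
    bottom, top = ground_truth_surfaces(config)

    xs = (np.arange(nx) + 0.5) * vnm
    ys = (np.arange(ny) + 0.5) * vnm
    zs = (np.arange(nz) + 0.5) * vnm
    X, Y = np.meshgrid(xs, ys)
    zb = bottom.evaluate(X, Y).astype(np.float32)
    zt = top.evaluate(X, Y).astype(np.float32)

    data = np.full((nz, ny, nx), AIR_LEVEL, dtype=np.float32)
    Zc = zs.astype(np.float32)[:, None, None]
    ice = (Zc >= zb[None]) & (Zc <= zt[None])
    data[ice] += ICE_DELTA

    cx, cy = nx * vnm / 2.0, ny * vnm / 2.0
    d = config.particle_diameter
    half_fov = min(nx, ny) * vnm / 2.0
    r_place = min(config.hole_radius, half_fov) - d / 2.0
    if r_place <= 0:
        raise InfeasibleConfigError("field of view too small for any particle")

    def _local_thickness(x, y):
        return float(top.evaluate(x, y) - bottom.evaluate(x, y))

    def _whole_particle_fits(x, y):
        return _local_thickness(x, y) >= d  # C4-thin areas exclude whole particles

    n_ads = int(round(config.n_particles * config.adsorbed_fraction))
    n_bot = int(round(n_ads * config.layer_split))
    n_top = n_ads - n_bot
    n_free = config.n_particles - n_ads + config.n_free_particles

    area = np.pi * r_place**2
    for side_n, side in ((n_bot, "bottom"), (n_top, "top")):
        sat = layer_saturation_percent(side_n, d, area)
        if sat > config.saturation_cap + 1e-9:
            raise InfeasibleConfigError(
                f"{side} layer: {side_n} particles request {sat:.0f}% saturation, "
                f"above the cap of {config.saturation_cap:.0f}%"
            )

    particles: list[TruthParticle] = []
    placed_xy: list[np.ndarray] = []

    def _place_layer(count: int, side: str) -> None:
        if count == 0:
            return
        xy = _poisson_disc(rng, count, r_place, (cx, cy), d, _whole_particle_fits)
        surf = bottom if side == "bottom" else top
        sgn = +1.0 if side == "bottom" else -1.0
        for x, y in xy:
            z = float(surf.evaluate(x, y)) + sgn * config.layer_offset
            particles.append(TruthParticle((float(x), float(y), z), (0, 0, 1),
                                           True, side, 0 if side == "bottom" else 1))
        placed_xy.append(xy)

    _place_layer(n_bot, "bottom")
    _place_layer(n_top, "top")

    # non-adsorbed particles: uniform in the mid-ice, clear of both surfaces
    tries, goal = 0, n_free
    budget = 200 * max(goal, 1)
    free_placed = 0
    while free_placed < goal:
        if tries >= budget:
            raise InfeasibleConfigError(
                f"could not place {goal} non-adsorbed particles clear of both "
                f"surfaces (ice too thin); placed {free_placed}"
            )
        tries += 1
        rr = r_place * np.sqrt(rng.uniform())
        th = rng.uniform(0, 2 * np.pi)
        x, y = cx + rr * np.cos(th), cy + rr * np.sin(th)
        lo = float(bottom.evaluate(x, y)) + d / 2.0 + config.layer_offset
        hi = float(top.evaluate(x, y)) - d / 2.0 - config.layer_offset
        if hi <= lo:
            continue
        z = rng.uniform(lo, hi)
        c = np.array([x, y, z])
        ok = all(
            np.sum((np.array(p.center) - c) ** 2) >= d * d for p in particles
        )
        if ok:
            particles.append(TruthParticle((float(x), float(y), float(z)),
                                           (0, 0, 1), False, "none", None))
            free_placed += 1

    n_all = len(particles)
    if n_all:
        orients = sample_orientations(config.orientation_model, n_all, rng)
        for p, v in zip(particles, orients):
            p.orientation = tuple(float(t) for t in v)
        centers = np.array([p.center for p in particles])
        _render_ellipsoids(data, centers, orients, d, config.particle_aspect,
                           vnm, PARTICLE_DELTA)

    # surface contamination: spheres sitting on the air side of each interface
    fov_area_um2 = (nx * vnm / 1000.0) * (ny * vnm / 1000.0)
    n_cont = int(round(config.contamination_density * fov_area_um2))
    if n_cont:
        for surf, sgn in ((bottom, -1.0), (top, +1.0)):
            cxy = rng.uniform([d, d], [nx * vnm - d, ny * vnm - d], size=(n_cont, 2))
            rads = rng.uniform(8.0, 18.0, size=n_cont)
            zc = np.array(
                [surf.evaluate(x, y) + sgn * r for (x, y), r in zip(cxy, rads)]
            )
            _render_spheres(data, np.column_stack([cxy, zc]), rads, vnm,
                            CONTAMINATION_DELTA)

    n_frag = int(round(config.fragment_density * fov_area_um2))
    if n_frag:
        for surf, sgn in ((bottom, -1.0), (top, +1.0)):
            cxy = rng.uniform([2, 2], [nx * vnm - 2, ny * vnm - 2], size=(n_frag, 2))
            rads = rng.uniform(1.5, 3.0, size=n_frag)
            zc = np.array(
                [surf.evaluate(x, y) - sgn * r for (x, y), r in zip(cxy, rads)]
            )
            _render_spheres(data, np.column_stack([cxy, zc]), rads, vnm,
                            FRAGMENT_DELTA)

    if config.noise_sigma > 0:
        data += rng.normal(0.0, config.noise_sigma, size=data.shape).astype(np.float32)

    if config.missing_wedge:
        data = _apply_missing_wedge(data, config.retained_tilt)

    n_adsorbed = sum(p.adsorbed for p in particles)
    realized_fraction = n_adsorbed / n_all if n_all else 0.0

    b_codes = []
    if any(not p.adsorbed for p in particles):
        b_codes.append("B1")
    if n_adsorbed:
        b_codes.append("B2" if config.orientation_model == "uniform" else "B3")
    a_code = "A2" if config.fragment_density > 0 else "A"

    gt = GroundTruth(
        particles=particles,
        surfaces={
            "bottom": {k: getattr(bottom, k) for k in ("a", "b", "c", "quad")}
            | {"center_xy": list(bottom.center_xy), "r_max": bottom.r_max},
            "top": {k: getattr(top, k) for k in ("a", "b", "c", "quad")}
            | {"center_xy": list(top.center_xy), "r_max": top.r_max},
        },
        thickness_center=config.thickness_center(),
        thickness_edge=config.thickness_edge(),
        taxonomy={
            "A": [a_code],
            "B": b_codes,
            "C_bottom": config.bottom_profile.curvature,
            "C_top": config.top_profile.curvature,
        },
        realized_adsorbed_fraction=realized_fraction,
        saturation={
            "bottom": layer_saturation_percent(n_bot, d, area),
            "top": layer_saturation_percent(n_top, d, area),
        },
        seed=config.seed,
        config=_config_to_dict(config),
    )
    return Volume(data, config.voxel_size), gt


def _config_to_dict(config: PhantomConfig) -> dict:
    d = asdict(config)
    if not isinstance(d["orientation_model"], str):
        d["orientation_model"] = [
            [list(map(float, mu)), float(k)] for mu, k in config.orientation_model
        ]
    d["volume_shape"] = list(config.volume_shape)
    return d


def config_from_dict(d: dict) -> PhantomConfig:
    d = dict(d)
    d["volume_shape"] = tuple(d["volume_shape"])
    for key in ("bottom_profile", "top_profile"):
        if isinstance(d[key], dict):
            d[key] = SurfaceProfile(**d[key])
    om = d.get("orientation_model", "uniform")
    if not isinstance(om, str):
        d["orientation_model"] = [(tuple(mu), k) for mu, k in om]
    return PhantomConfig(**d)


def write_ground_truth(gt: GroundTruth, path: str) -> None:
    """Serialize a :class:`GroundTruth` to a JSON sidecar."""
    with open(path, "w") as fh:
        json.dump(gt.to_dict(), fh, indent=1)


def read_ground_truth(path: str) -> GroundTruth:
    with open(path) as fh:
        return GroundTruth.from_dict(json.load(fh))


def write_particle_table(gt: GroundTruth, path: str) -> None:
    """Particle truth as CSV: x_nm,y_nm,z_nm,vx,vy,vz,adsorbed,side,layer."""
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["x_nm", "y_nm", "z_nm", "vx", "vy", "vz", "adsorbed", "side", "layer"])
        for p in gt.particles:
            w.writerow(
                [*(f"{v:.3f}" for v in p.center), *(f"{v:.6f}" for v in p.orientation),
                 int(p.adsorbed), p.side, "" if p.layer_id is None else p.layer_id]
            )
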