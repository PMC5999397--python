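"""Air-water interface location, ice thickness, tilt and curvature.

A vitrified film in a grid hole is bounded by two air-water interfaces.
This module finds the two interfaces in a tomographic volume, models each
as a tilted plane with an optional radially-quadratic bowl term,

    z(x, y) = a*x + b*y + c + q * r^2,      r^2 = (x-x0)^2 + (y-y0)^2,

and derives the quantities used for grid screening: a thickness map over
the hole, minimum thickness at the hole centre and near the hole edge,
the tilt of each interface relative to the beam axis, and a curvature
class per interface:

    C1  interface bulges outward (ice thicker at the hole centre),
    C2  flat,
    C3  interface recessed inward (ice thinner at the centre),
    C4  as C3 but with centre ice thinner than the particle minor axis,
        so whole particles no longer fit there.

Conventions: z is the beam axis, the *bottom* interface has the lower z,
all inputs and outputs are in nanometres, and measurements carry the
survey's nominal errors (5 nm thickness, 1 degree tilt).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .volume import Volume

__all__ = [
    "InterfaceSurface",
    "IceGeometry",
    "AmbiguousInterfacesError",
    "fit_surface",
    "surface_tilt",
    "z_profile",
    "locate_interfaces",
    "thickness_stats",
]

#: nominal per-measurement errors of the screening procedure
THICKNESS_MEASUREMENT_ERROR_NM = 5.0
TILT_MEASUREMENT_ERROR_DEG = 1.0

#: |mean centre height - mean edge height| below which an interface counts as flat
CURVATURE_FLAT_TOL_NM = 5.0

#: edge annulus sits nominally this far inside the hole rim
EDGE_INSET_NM = 100.0

#: centre disc radius as a fraction of the hole radius
CENTER_DISC_FRACTION = 0.2


class AmbiguousInterfacesError(RuntimeError):
    """Fewer than two usable interface boundaries were found.

    ``candidates`` holds the scored boundary candidates that were seen.
    """

    def __init__(self, message: str, candidates: list[tuple[float, float]] | None = None):
        super().__init__(message)
        self.candidates = candidates or []


@dataclass
class InterfaceSurface:
    """One fitted air-water interface.

    ``side`` is ``"bottom"`` (lower z) or ``"top"``.  ``locator`` records
    how the surface was found: ``gradient`` (density step), ``contamination``
    (surface ice contamination), ``particle_layer`` (adsorbed layer plus an
    offset hint), or ``analytic`` (known ground truth).
    """

    side: str
    a: float = 0.0
    b: float = 0.0
    c: float = 0.0
    quad: float = 0.0
    center_xy: tuple[float, float] = (0.0, 0.0)
    r_max: float | None = None  # clamp radius for the quadratic term (hole rim)
    fit_residual: float = 0.0
    locator: str = "analytic"
    support_points: int = 0
    candidates: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.side not in ("bottom", "top"):
            raise ValueError(f"side must be 'bottom' or 'top', got {self.side!r}")
        if self.fit_residual < 0:
            raise ValueError("fit residual must be >= 0")

    def evaluate(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Surface height z (nm) at positions (x, y) in nm."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        x0, y0 = self.center_xy
        r2 = (x - x0) ** 2 + (y - y0) ** 2
        if self.r_max is not None:
            r2 = np.minimum(r2, self.r_max**2)
        return self.a * x + self.b * y + self.c + self.quad * r2

    def shifted(self, dz: float) -> "InterfaceSurface":
        """Same surface translated along z by *dz* nm."""
        s = InterfaceSurface(**{**asdict(self), "c": self.c + dz})
        return s

    @property
    def tilt_deg(self) -> float:
        return surface_tilt(self)


def surface_tilt(surface: InterfaceSurface) -> float:
    """Absolute angle (degrees) between the surface normal and the beam axis.

    Only the plane component is used; the angle is in [0, 90).  For a plane
    z = a*x + b*y + c the normal is (-a, -b, 1)/||.||, so the tilt is
    arccos(1 / sqrt(1 + a^2 + b^2)).
    """
    a, b = surface.a, surface.b
    return math.degrees(math.acos(1.0 / math.sqrt(1.0 + a * a + b * b)))


def fit_surface(
    points: np.ndarray,
    order: int = 1,
    center_xy: tuple[float, float] = (0.0, 0.0),
    side: str = "bottom",
    locator: str = "gradient",
    trim_sigma: float = 0.0,
) -> InterfaceSurface:
    """Least-squares fit of a surface model to (x, y, z) points in nm.

    ``order=1`` fits a plane; ``order=2`` adds the radially-quadratic term
    about ``center_xy``.  The residual is the RMS misfit in z.  With
    ``trim_sigma > 0`` one refit pass drops points whose residual exceeds
    ``trim_sigma`` times the RMS (outlier rejection).
    """
    if trim_sigma > 0:
        first = fit_surface(points, order, center_xy, side, locator)
        pts = np.asarray(points, dtype=float)
        resid = pts[:, 2] - first.evaluate(pts[:, 0], pts[:, 1])
        rms = float(np.sqrt(np.mean(resid**2)))
        keep = np.abs(resid) <= trim_sigma * max(rms, 1e-9)
        need = 3 if order == 1 else 6
        if keep.sum() >= need and keep.sum() < len(pts):
            try:
                return fit_surface(pts[keep], order, center_xy, side, locator)
            except ValueError:
                return first
        return first
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("points must be an (n, 3) array of x, y, z")
    n = pts.shape[0]
    need = 3 if order == 1 else 4
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    if n < need:
        raise ValueError(f"need at least {need} points for order {order}, got {n}")
    x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
    cols = [x, y, np.ones(n)]
    if order == 2:
        x0, y0 = center_xy
        cols.append((x - x0) ** 2 + (y - y0) ** 2)
    A = np.column_stack(cols)
    # degenerate (collinear in xy) configurations have rank < columns
    if np.linalg.matrix_rank(A) < A.shape[1]:
        raise ValueError("degenerate point configuration (collinear or coincident)")
    coef, _, _, _ = np.linalg.lstsq(A, z, rcond=None)
    resid = float(np.sqrt(np.mean((A @ coef - z) ** 2)))
    quad = float(coef[3]) if order == 2 else 0.0
    return InterfaceSurface(
        side=side,
        a=float(coef[0]),
        b=float(coef[1]),
        c=float(coef[2]),
        quad=quad,
        center_xy=center_xy,
        fit_residual=resid,
        locator=locator,
        support_points=n,
    )


def z_profile(vol: Volume, mask: np.ndarray | None = None) -> np.ndarray:
    """Robust per-slice density statistic (median over masked columns).

    Returns one value per z slice.  ``mask`` is a 2D boolean (y, x) hole
    mask; ``None`` uses the full field of view.
    """
    nz, ny, nx = vol.shape
    if mask is None:
        mask = np.ones((ny, nx), dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (ny, nx):
        raise ValueError(f"mask shape {mask.shape} does not match volume {(ny, nx)}")
    if not mask.any():
        raise ValueError("empty mask")
    return np.median(vol.data[:, mask], axis=1)


def _boundary_candidates(profile: np.ndarray, smooth: float = 2.0) -> list[tuple[float, float]]:
    """Scored candidate boundary slices from a z profile.

    Candidates are extrema of the smoothed derivative whose magnitude
    exceeds 25% of the strongest one; scores are |d profile / dz|.
    """
    p = ndimage.gaussian_filter1d(profile.astype(float), smooth)
    dp = np.gradient(p)
    mag = np.abs(dp)
    if mag.max() == 0:
        return []
    thr = 0.25 * mag.max()
    cands: list[tuple[float, float]] = []
    for i in range(1, len(dp) - 1):
        if mag[i] >= thr and mag[i] >= mag[i - 1] and mag[i] > mag[i + 1]:
            cands.append((float(i), float(mag[i])))
    return cands


def _slab_bounds(profile: np.ndarray) -> tuple[int, int, list[tuple[float, float]]]:
    """Coarse (z_lo, z_hi) slice bounds of the ice slab from a z profile.

    The ice is denser (darker, more negative) than the surrounding air, so
    the slab is the region below the midpoint between the air level and the
    slab level.  When more than two boundary candidates exist, the outermost
    pair enclosing the densest slab is kept and all candidates are reported.
    """
    cands = _boundary_candidates(profile)
    if len(cands) < 2:
        raise AmbiguousInterfacesError(
            f"found {len(cands)} boundary candidate(s); need 2", cands
        )
    nz = len(profile)
    edge = max(2, nz // 32)
    air = float(np.median(np.concatenate([profile[:edge], profile[-edge:]])))
    lo_level = float(np.percentile(profile, 10))
    half = 0.5 * (air + lo_level)
    below = profile < half
    if not below.any():
        raise AmbiguousInterfacesError("no dense slab below the air level", cands)
    # densest contiguous run below the threshold
    runs: list[tuple[int, int, float]] = []
    i = 0
    while i < nz:
        if below[i]:
            j = i
            while j + 1 < nz and below[j + 1]:
                j += 1
            runs.append((i, j, float(profile[i : j + 1].mean())))
            i = j + 1
        else:
            i += 1
    lo, hi, _ = min(runs, key=lambda r: r[2])  # densest = most negative mean
    # outermost candidate pair enclosing that slab
    left = [z for z, _ in cands if z <= lo + 1]
    right = [z for z, _ in cands if z >= hi - 1]
    if not left or not right:
        return lo, hi, cands
    return int(min(left)), int(max(right)), cands


def _densest_run(below: np.ndarray, prof: np.ndarray) -> tuple[int, int] | None:
    """Longest-scoring contiguous True run: the darkest slab in a profile."""
    runs: list[tuple[int, int, float]] = []
    i, n = 0, len(below)
    while i < n:
        if below[i]:
            j = i
            while j + 1 < n and below[j + 1]:
                j += 1
            runs.append((i, j, float(prof[i : j + 1].mean())))
            i = j + 1
        else:
            i += 1
    if not runs:
        return None
    lo, hi, _ = min(runs, key=lambda r: (r[2], -(r[1] - r[0])))
    return lo, hi


def _refine_patches(
    vol: Volume,
    mask: np.ndarray,
    patch: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-patch sub-voxel boundary z positions (nm) for both interfaces.

    The masked field of view is tiled into ``patch`` x ``patch`` blocks of
    columns; each block's averaged profile is thresholded halfway between
    its air and ice levels, the densest contiguous below-half run is taken
    as the local slab, and the two crossings are interpolated.  Returns
    (bottom_points, top_points) as (n, 3) arrays of x, y, z in nm.
    """
    nz, ny, nx = vol.shape
    vnm = vol.voxel_nm
    data = vol.data
    bot_pts: list[tuple[float, float, float]] = []
    top_pts: list[tuple[float, float, float]] = []
    for iy in range(0, ny - patch + 1, patch):
        for ix in range(0, nx - patch + 1, patch):
            sub = mask[iy : iy + patch, ix : ix + patch]
            if not sub.all():
                continue
            block = data[:, iy : iy + patch, ix : ix + patch]
            # median over columns: robust against the dark particle layers
            # that cover a large fraction of the area near each interface
            prof = np.median(block.reshape(nz, -1), axis=1)
            prof = ndimage.gaussian_filter1d(prof, 1.0)
            edge = max(2, nz // 32)
            air = float(np.median(np.concatenate([prof[:edge], prof[-edge:]])))
            ice = float(np.percentile(prof, 10))
            if not ice < air - 1e-12:
                continue
            half = 0.5 * (air + ice)
            run = _densest_run(prof < half, prof)
            if run is None:
                continue
            zb_i, zt_i = run

            def _cross(i_out: int, i_in: int) -> float:
                p0, p1 = prof[i_out], prof[i_in]
                if abs(p1 - p0) < 1e-12:
                    return float(i_in)
                t = (half - p0) / (p1 - p0)
                return i_out + float(np.clip(t, 0.0, 1.0)) * (i_in - i_out)

            zb = _cross(zb_i - 1, zb_i) if zb_i > 0 else float(zb_i)
            zt = _cross(zt_i + 1, zt_i) if zt_i < nz - 1 else float(zt_i)
            cx = (ix + patch / 2.0) * vnm
            cy = (iy + patch / 2.0) * vnm
            bot_pts.append((cx, cy, (zb + 0.5) * vnm))
            top_pts.append((cx, cy, (zt + 0.5) * vnm))
    return np.array(bot_pts), np.array(top_pts)


def _column_face(
    data: np.ndarray, iz: int, iy: int, ix: int, step: int, ice_level: float, vnm: float
) -> float | None:
    """Face z (nm) for one column: where the density recovers from the blob
    level to halfway toward the ice level, walking in the ice direction."""
    nz = data.shape[0]
    col = ndimage.gaussian_filter1d(
        data[:, iy - 1 : iy + 2, ix - 1 : ix + 2].mean(axis=(1, 2)), 1.0
    )
    seg_len = max(2, int(25.0 / vnm))
    seg = col[iz :: step][:seg_len]
    if len(seg) < 2:
        return None
    i0 = iz + step * int(np.argmin(seg))
    blob_level = float(col[i0])
    if blob_level >= ice_level - 0.1:
        return None
    half = 0.5 * (blob_level + ice_level)
    i = i0
    while 0 <= i + step < nz:
        j = i + step
        if col[j] >= half:
            t = (half - col[i]) / (col[j] - col[i])
            return (i + t * step + 0.5) * vnm
        i = j
    return None


def _blob_ice_face(
    vol: Volume, x: float, y: float, z: float, toward_ice: bool, ice_level: float
) -> float | None:
    """z (nm) of a contamination blob's face nearest the vitreous ice.

    Several columns through the blob are walked in the ice direction; the
    face is the extreme crossing toward the ice, which approximates the
    tangent point of a roughly spherical blob resting on the interface
    (any off-centre column only reaches a chord, biased away from the ice).
    """
    vnm = vol.voxel_nm
    nz, ny, nx = vol.shape
    iz = int(z / vnm)
    if not (0 <= iz < nz):
        return None
    step = 1 if toward_ice else -1
    faces = []
    off_vox = max(1, int(round(3.0 / vnm)))
    for dy in (-off_vox, 0, off_vox):
        for dx in (-off_vox, 0, off_vox):
            iy = int(np.clip(y / vnm + dy, 1, ny - 2))
            ix = int(np.clip(x / vnm + dx, 1, nx - 2))
            f = _column_face(vol.data, iz, iy, ix, step, ice_level, vnm)
            if f is not None:
                faces.append(f)
    if not faces:
        return None
    return max(faces) if toward_ice else min(faces)


def _refine_particle_z(
    vol: Volume, x: float, y: float, z: float, diam: float
) -> float | None:
    """Refine a detection's z against the nearby interface density step.

    A particle adsorbed close to an interface sits on a background step
    (air on one side, ice on the other) that biases blob centroids toward
    the ice.  Removing a linear baseline across a local window and taking
    the centre of mass of the remaining dark excess is unbiased.
    """
    vnm = vol.voxel_nm
    nz, ny, nx = vol.shape
    half = int(round(0.8 * diam / vnm))
    iz = int(z / vnm)
    iy = int(np.clip(y / vnm, 1, ny - 2))
    ix = int(np.clip(x / vnm, 1, nx - 2))
    lo, hi = iz - half, iz + half + 1
    if lo < 1 or hi > nz - 1:
        return None
    col = vol.data[lo:hi, iy - 1 : iy + 2, ix - 1 : ix + 2].mean(axis=(1, 2))
    col = ndimage.gaussian_filter1d(col, 1.5)
    i = int(np.argmin(col))
    if i == 0 or i == len(col) - 1:
        return None
    # parabolic vertex through the minimum and its neighbours
    y0, y1, y2 = col[i - 1], col[i], col[i + 1]
    denom = y0 - 2 * y1 + y2
    frac = 0.0 if abs(denom) < 1e-12 else 0.5 * (y0 - y2) / denom
    return (lo + i + float(np.clip(frac, -1.0, 1.0)) + 0.5) * vnm


def locate_interfaces(
    vol: Volume,
    strategy: str = "gradient",
    mask: np.ndarray | None = None,
    hints: dict | None = None,
    bin_factor: int = 1,
    order: int = 2,
    patch: int = 16,
) -> tuple[InterfaceSurface, InterfaceSurface]:
    """Locate the bottom and top air-water interfaces of a volume.

    Strategies
    ----------
    ``gradient``
        Density step between air and ice, refined per patch of columns and
        fitted with :func:`fit_surface`.
    ``contamination``
        Surface contamination blobs anchor each interface at the blob face
        nearest the vitreous ice (needs >= 3 blobs per side).
    ``particle_layer``
        An adsorbed particle layer plus a layer-offset hint
        (``hints={"layer_offset": nm, "particle_diameter": nm}``); the
        interface lies one offset outside the fitted layer plane.  Sides
        without a detected layer fall back to the gradient surface.

    Returns (bottom, top) with bottom below top everywhere in the mask.
    """
    if bin_factor > 1:
        vol = vol.binned(bin_factor)
    nz, ny, nx = vol.shape
    vnm = vol.voxel_nm
    if mask is None:
        mask = np.ones((ny, nx), dtype=bool)
    cx = nx * vnm / 2.0
    cy = ny * vnm / 2.0
    hints = hints or {}

    if strategy == "gradient":
        prof = z_profile(vol, mask)
        _, _, cands = _slab_bounds(prof)  # validates that two boundaries exist
        bot_pts, top_pts = _refine_patches(vol, mask, patch)
        if len(bot_pts) < (3 if order == 1 else 6):
            raise AmbiguousInterfacesError(
                f"only {len(bot_pts)} patch boundary points found", cands
            )
        bottom = fit_surface(bot_pts, order=order, center_xy=(cx, cy),
                             side="bottom", locator="gradient", trim_sigma=2.5)
        top = fit_surface(top_pts, order=order, center_xy=(cx, cy),
                          side="top", locator="gradient", trim_sigma=2.5)
        bottom.candidates = cands
        top.candidates = cands
        _check_order(bottom, top, cx, cy)
        return bottom, top

    if strategy == "contamination":
        from .particles import detect_particles  # local import; no cycle at module load

        # contamination blobs are large (>= 8 nm) dark features outside the slab
        prof = z_profile(vol, mask)
        z_lo, z_hi, _ = _slab_bounds(prof)
        blobs = detect_particles(vol, diameter_range=(8.0, 40.0), n_scales=5)
        if len(blobs) == 0:
            raise AmbiguousInterfacesError("no contamination blobs detected")
        z_mid = 0.5 * (z_lo + z_hi + 1) * vnm
        ice_level = float(np.percentile(prof[z_lo : z_hi + 1], 50))
        anchors_b, anchors_t = [], []
        for x, y, z, diam, _score in blobs:
            face = _blob_ice_face(vol, x, y, z, toward_ice=(z < z_mid),
                                  ice_level=ice_level)
            if face is None:
                continue
            if z < z_mid:
                anchors_b.append((x, y, face))
            else:
                anchors_t.append((x, y, face))
        if len(anchors_b) < 3 or len(anchors_t) < 3:
            raise AmbiguousInterfacesError(
                f"need >=3 contamination blobs per surface, got "
                f"{len(anchors_b)} bottom / {len(anchors_t)} top"
            )
        r_eff = min(cx, cy)

        def _fit_anchors(anchors: list, side: str) -> InterfaceSurface:
            pts = np.array(anchors)
            if len(pts) < 5:
                return fit_surface(pts, order=1, center_xy=(cx, cy), side=side,
                                   locator="contamination")
            # plane + bowl, with the bowl coefficient weakly ridge-regularized:
            # few scattered anchors can leave it ill-conditioned (anchor noise
            # ~1.5 nm against bowls of a few tens of nm over the field)
            x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
            r2 = (x - cx) ** 2 + (y - cy) ** 2
            A = np.column_stack([x, y, np.ones(len(pts)), r2])
            kappa = 1.5 * r_eff**2 / 60.0
            A_aug = np.vstack([A, [0.0, 0.0, 0.0, kappa]])
            z_aug = np.concatenate([z, [0.0]])
            coef, *_ = np.linalg.lstsq(A_aug, z_aug, rcond=None)
            resid = float(np.sqrt(np.mean((A @ coef - z) ** 2)))
            if len(pts) >= 9:  # one trim pass when spares exist
                r = A @ coef - z
                keep = np.abs(r) <= 2.0 * max(resid, 1e-9)
                if 6 <= keep.sum() < len(pts):
                    coef, *_ = np.linalg.lstsq(
                        np.vstack([A[keep], [0.0, 0.0, 0.0, kappa]]),
                        np.concatenate([z[keep], [0.0]]), rcond=None)
                    resid = float(np.sqrt(np.mean((A[keep] @ coef - z[keep]) ** 2)))
            return InterfaceSurface(
                side=side, a=float(coef[0]), b=float(coef[1]), c=float(coef[2]),
                quad=float(coef[3]), center_xy=(cx, cy), fit_residual=resid,
                locator="contamination", support_points=len(pts),
            )

        bottom = _fit_anchors(anchors_b, "bottom")
        top = _fit_anchors(anchors_t, "top")
        _check_order(bottom, top, cx, cy)
        return bottom, top

    if strategy == "particle_layer":
        from .particles import detect_particles

        offset = float(hints.get("layer_offset", 5.0))
        diam = float(hints.get("particle_diameter", 10.0))
        dets = detect_particles(vol, diameter_range=(0.6 * diam, 1.6 * diam))
        if len(dets) >= 3:
            # keep confident detections: residual step artifacts score far
            # below the true particles that dominate the count
            dets = dets[dets[:, 4] >= 0.4 * np.median(dets[:, 4])]
        if len(dets) < 3:
            raise AmbiguousInterfacesError(
                f"particle_layer strategy needs >=3 particles, got {len(dets)}"
            )
        pts = dets[:, :3].copy()
        for i, (x, y, z) in enumerate(pts):
            zr = _refine_particle_z(vol, x, y, z, diam)
            if zr is not None:
                pts[i, 2] = zr
        grad_b, grad_t = locate_interfaces(vol, "gradient", mask=mask, order=order,
                                           patch=patch)
        # one layer or two?  A single (possibly curved) layer fits one
        # plane-plus-bowl surface with a small robust spread; two layers
        # leave bimodal residuals at half their separation.  MAD, not RMS:
        # a few stray detections must not flip the decision.
        order_all = 2 if len(pts) >= 8 else 1
        plane_all = fit_surface(pts, order=order_all, center_xy=(cx, cy))
        resid_all = pts[:, 2] - plane_all.evaluate(pts[:, 0], pts[:, 1])
        rob = 1.4826 * float(np.median(np.abs(resid_all - np.median(resid_all))))
        single = rob < 0.35 * diam
        if single:
            zc = float(np.mean(pts[:, 2]))
            side = (
                "bottom"
                if abs(zc - grad_b.evaluate(cx, cy)) < abs(zc - grad_t.evaluate(cx, cy))
                else "top"
            )
            lower = pts if side == "bottom" else np.empty((0, 3))
            upper = pts if side == "top" else np.empty((0, 3))
        else:
            lower = pts[resid_all <= 0]
            upper = pts[resid_all > 0]

        def _from_layer(layer_pts: np.ndarray, side: str) -> InterfaceSurface:
            if len(layer_pts) < 3:
                return grad_b if side == "bottom" else grad_t
            # an adsorbed layer follows the (possibly curved) interface, so
            # fit plane + bowl when enough particles support it
            o = 2 if len(layer_pts) >= 8 else 1
            trim = 2.5 if len(layer_pts) >= (11 if o == 2 else 6) else 0.0
            layer = fit_surface(layer_pts, order=o, center_xy=(cx, cy),
                                side=side, locator="particle_layer",
                                trim_sigma=trim)
            # the interface is one offset outside the layer surface
            return layer.shifted(-offset if side == "bottom" else +offset)

        bottom = _from_layer(lower, "bottom")
        top = _from_layer(upper, "top")
        _check_order(bottom, top, cx, cy)
        return bottom, top

    raise ValueError(f"unknown strategy {strategy!r}")


def _check_order(bottom: InterfaceSurface, top: InterfaceSurface, cx: float, cy: float) -> None:
    if bottom.evaluate(cx, cy) >= top.evaluate(cx, cy):
        raise AmbiguousInterfacesError("bottom surface is not below top at the hole centre")


@dataclass
class IceGeometry:
    """Ice thickness, tilt and curvature summary for one hole region."""

    thickness_map: np.ndarray  # nm, NaN outside the hole mask
    t_center_min: float
    t_edge_min: float
    curvature_bottom: str
    curvature_top: str
    tilt_bottom: float
    tilt_top: float
    hole_center_xy: tuple[float, float]
    hole_radius: float
    edge_annulus_radius: float
    degenerate: bool = False
    measurement_error: float = THICKNESS_MEASUREMENT_ERROR_NM

    def to_dict(self) -> dict:
        d = asdict(self)
        d["thickness_map"] = None  # maps are written separately as images
        d["units"] = {"thickness": "nm", "tilt": "deg"}
        return d


def thickness_stats(
    bottom: InterfaceSurface,
    top: InterfaceSurface,
    x_nm: np.ndarray,
    y_nm: np.ndarray,
    hole_center_xy: tuple[float, float],
    hole_radius: float,
    particle_minor_axis: float,
    edge_inset: float = EDGE_INSET_NM,
    annulus_halfwidth: float = 10.0,
    flat_tol: float = CURVATURE_FLAT_TOL_NM,
) -> IceGeometry:
    """Thickness map, centre/edge minima, tilts and curvature classes.

    ``x_nm`` / ``y_nm`` are the coordinate axes of the analysis grid.  The
    centre region is a disc of radius 20% of the hole radius; the edge
    annulus nominally sits ``edge_inset`` (~100 nm) inside the hole rim,
    clipped to 60% of the hole radius for small (scaled-down) holes so the
    annulus stays distinct from the centre disc.  Crossing surfaces are
    reported as degenerate with zeroed thickness, not raised.
    """
    X, Y = np.meshgrid(np.asarray(x_nm, float), np.asarray(y_nm, float))
    x0, y0 = hole_center_xy
    r = np.hypot(X - x0, Y - y0)
    hole = r <= hole_radius
    zb = bottom.evaluate(X, Y)
    zt = top.evaluate(X, Y)
    thick = zt - zb
    degenerate = bool((thick[hole] < 0).any())
    thick = np.clip(thick, 0.0, None)
    tmap = np.where(hole, thick, np.nan)

    rc = CENTER_DISC_FRACTION * hole_radius
    center = hole & (r <= rc)
    r_edge = max(hole_radius - edge_inset, 0.6 * hole_radius)
    edge = hole & (np.abs(r - r_edge) <= annulus_halfwidth)
    if not center.any() or not edge.any():
        raise ValueError("analysis grid too coarse for centre disc / edge annulus")

    t_center_min = float(np.min(thick[center]))
    t_edge_min = float(np.min(thick[edge]))

    def _curvature(surface: InterfaceSurface, sign: float) -> str:
        # remove the common tilt plane so only the bowl shape is compared
        h = surface.evaluate(X, Y) - (surface.a * X + surface.b * Y)
        delta = float(h[center].mean() - h[edge].mean())
        outward = sign * delta  # positive when bulging away from the ice
        if outward > flat_tol:
            return "C1"
        if outward < -flat_tol:
            return "C4" if t_center_min < particle_minor_axis else "C3"
        return "C2"

    curv_b = _curvature(bottom, -1.0)  # bottom bulges outward = downward
    curv_t = _curvature(top, +1.0)
    if degenerate:
        curv_b = curv_t = "C4"

    return IceGeometry(
        thickness_map=tmap,
        t_center_min=t_center_min,
        t_edge_min=t_edge_min,
        curvature_bottom=curv_b,
        curvature_top=curv_t,
        tilt_bottom=surface_tilt(bottom),
        tilt_top=surface_tilt(top),
        hole_center_xy=(float(x0), float(y0)),
        hole_radius=float(hole_radius),
        edge_annulus_radius=float(r_edge),
        degenerate=degenerate,
    )
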