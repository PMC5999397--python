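"""Preferred-orientation statistics and tilt-expanded angular coverage.

Adsorption to an air-water interface often restricts particles to a few
preferred orientations.  This module quantifies that restriction from the
per-particle orientation axes (mean resultant length, mode clustering on
the sphere) and computes how much of the projection hemisphere a set of
preferred orientations covers once the local interface tilts observed on
real grids (a few degrees, up to ~16) are folded in — tilted interfaces
effectively multiply the imaged views of a preferentially oriented
particle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

__all__ = [
    "OrientationStats",
    "orientation_dispersion",
    "cluster_modes",
    "tilt_expanded_coverage",
]

#: angular bandwidth (deg) of the on-sphere mode clustering
MODE_BANDWIDTH_DEG = 15.0

# R thresholds mapping to the survey's qualitative no/some/yes judgement
R_NONE_MAX = 0.2
R_STRONG_MIN = 0.6


@dataclass
class OrientationStats:
    n: int
    resultant_length: float  # R in [0, 1]
    mode_count: int
    modes: list[tuple[float, float, float]] = field(default_factory=list)
    weights: list[float] = field(default_factory=list)  # normalized over modes
    mode_mass: float = 0.0  # fraction of all vectors inside detected modes
    dispersion_class: str = "none"  # none | some | strong

    def __post_init__(self) -> None:
        if not (0.0 <= self.resultant_length <= 1.0 + 1e-9):
            raise ValueError("resultant length must be in [0, 1]")
        if self.n >= 1 and self.mode_count < 1:
            raise ValueError("mode_count must be >= 1 for nonempty samples")


def _check_unit(vectors: np.ndarray) -> np.ndarray:
    v = np.asarray(vectors, dtype=float).reshape(-1, 3)
    norms = np.linalg.norm(v, axis=1)
    if not np.allclose(norms, 1.0, atol=1e-6):
        raise ValueError("orientation vectors must be unit length")
    return v


def cluster_modes(
    vectors: np.ndarray,
    bandwidth_deg: float = MODE_BANDWIDTH_DEG,
    axial: bool = False,
    min_mass: float = 0.05,
) -> tuple[list[np.ndarray], list[float]]:
    """Density-based orientation modes on the sphere.

    Average-linkage clustering on angular distance, cut at twice the
    bandwidth; clusters holding at least ``min_mass`` of the vectors (and
    at least 2 members) become modes.  With ``axial=True``, antipodal
    vectors are identified before clustering (sign-ambiguous axes).
    Always returns at least one mode for nonempty input.
    """
    v = _check_unit(vectors)
    n = len(v)
    if n == 0:
        return [], []
    if axial:
        v = v * np.where(v[:, 2:3] >= 0, 1.0, -1.0)
    if n == 1:
        return [v[0]], [1.0]

    def _ang(u, w):
        c = abs(u @ w) if axial else u @ w
        return math.degrees(math.acos(min(1.0, max(-1.0, c))))

    d = pdist(v, metric=_ang)
    Z = linkage(d, method="average")
    labels = fcluster(Z, t=2.0 * bandwidth_deg, criterion="distance")
    modes: list[np.ndarray] = []
    weights: list[float] = []
    for lab in np.unique(labels):
        members = v[labels == lab]
        if len(members) < max(2, int(min_mass * n)):
            continue
        m = members.mean(axis=0)
        nrm = np.linalg.norm(m)
        if nrm < 1e-9:
            continue
        m = m / nrm
        # a genuine mode is compact: mean angular spread within the bandwidth
        cosang = np.clip(np.abs(members @ m) if axial else members @ m, -1.0, 1.0)
        spread = float(np.degrees(np.arccos(cosang)).mean())
        if spread > bandwidth_deg:
            continue
        modes.append(m)
        weights.append(len(members) / n)
    if not modes:  # fall back to the largest cluster
        counts = np.bincount(labels)
        lab = int(np.argmax(counts[1:]) + 1)
        members = v[labels == lab]
        m = members.mean(axis=0)
        nrm = np.linalg.norm(m)
        modes = [m / nrm if nrm > 1e-9 else np.array([0.0, 0.0, 1.0])]
        weights = [len(members) / n]
    order = np.argsort(weights)[::-1]
    return [modes[i] for i in order], [weights[i] for i in order]


def orientation_dispersion(vectors: np.ndarray, axial: bool = False) -> OrientationStats:
    """Dispersion statistics of orientation axes.

    R = |sum v| / n for directed vectors; with ``axial=True`` (vectors with
    sign ambiguity) the axial concentration (3*lambda_max - 1)/2 of the
    orientation matrix is used instead.  Class mapping: R < 0.2 none,
    0.2-0.6 some, > 0.6 strong.
    """
    v = _check_unit(vectors)
    n = len(v)
    if n < 1:
        raise ValueError("need at least one vector")
    if axial:
        T = (v[:, :, None] * v[:, None, :]).mean(axis=0)
        lam = float(np.linalg.eigvalsh(T)[-1])
        R = max(0.0, (3.0 * lam - 1.0) / 2.0)
    else:
        R = float(np.linalg.norm(v.sum(axis=0)) / n)
    if R < R_NONE_MAX:
        klass = "none"
    elif R <= R_STRONG_MIN:
        klass = "some"
    else:
        klass = "strong"
    modes, weights = cluster_modes(v, axial=axial)
    mode_mass = float(sum(weights))
    # weights are reported over detected modes only
    tot = sum(weights)
    weights = [w / tot for w in weights] if tot > 0 else weights
    return OrientationStats(
        n=n,
        resultant_length=min(R, 1.0),
        mode_count=len(modes),
        modes=[tuple(map(float, m)) for m in modes],
        weights=weights,
        mode_mass=min(mode_mass, 1.0),
        dispersion_class=klass,
    )


def _fibonacci_hemisphere(n: int) -> np.ndarray:
    """Quasi-uniform points on the upper hemisphere (equal-area)."""
    i = np.arange(n) + 0.5
    z = i / n  # cos(theta) uniform in (0, 1): upper hemisphere, equal area
    phi = i * math.pi * (3.0 - math.sqrt(5.0))
    s = np.sqrt(1.0 - z * z)
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), z])


def tilt_expanded_coverage(
    modes: list | np.ndarray,
    symmetry_order: int = 1,
    tilts: list[float] | None = None,
    bandwidth: float = 5.0,
    n_grid: int = 8000,
) -> float:
    """Fraction of the projection hemisphere covered by preferred views.

    Each mode is replicated under the cyclic symmetry (C_k about the z
    axis).  A stage/interface tilt by alpha sweeps an annulus of angular
    radius alpha around each mode (in-plane rotation marginalized), so a
    grid direction is covered when its axial angular distance to some mode
    lies within ``bandwidth`` of some tilt.  Directions are treated as
    axes (u and -u identified).  Evaluated by equal-area quadrature on a
    Fibonacci hemisphere grid.
    """
    if tilts is None:
        tilts = [0.0]
    if symmetry_order < 1:
        raise ValueError("symmetry_order must be >= 1")
    for t in tilts:
        if not (0.0 <= t < 90.0):
            raise ValueError("tilts must be in [0, 90)")
    modes = np.asarray(modes, dtype=float).reshape(-1, 3)
    if len(modes) == 0:
        raise ValueError("empty mode list")
    modes = modes / np.linalg.norm(modes, axis=1, keepdims=True)
    # replicate under C_k about z
    reps = []
    for j in range(symmetry_order):
        ang = 2.0 * math.pi * j / symmetry_order
        c, s = math.cos(ang), math.sin(ang)
        Rz = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        reps.append(modes @ Rz.T)
    all_modes = np.vstack(reps)
    grid = _fibonacci_hemisphere(n_grid)
    cosd = np.abs(grid @ all_modes.T)  # axial distance
    dist = np.degrees(np.arccos(np.clip(cosd, -1.0, 1.0)))  # (n_grid, n_modes)
    covered = np.zeros(n_grid, dtype=bool)
    for t in tilts:
        covered |= (np.abs(dist - t) <= bandwidth).any(axis=1)
    return float(covered.mean())
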