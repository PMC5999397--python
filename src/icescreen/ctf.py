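"""Acquisition-physics calculators for defocus-error resolution budgets.

When every particle in a field of view does not sit at the defocus the
whole image was corrected with — because two layers straddle the midway
defocus estimate, or because the particle layer is tilted — the residual
defocus error dz dephases the contrast transfer function.  The usable
resolution is taken as the spatial frequency where two CTFs differing by
dz are 90 degrees out of phase:

    pi * lambda * dz * s^2 = pi/2   =>   d = 1/s = sqrt(2 * lambda * dz)

independent of spherical aberration and of the common defocus, since
these cancel in the phase difference.  The module also provides the
cosine dose scheme used for tilt-series collection.

Units follow cryoEM practice: kV for voltage, Å for wavelength and
spatial quantities unless a name says nm or µm, e-/Å^2 for dose.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "CtfParams",
    "electron_wavelength",
    "ctf_phase",
    "defocus_error_resolution_limit",
    "tilt_defocus_offset",
    "bilayer_defocus_offset",
    "duplicate_defocus_candidates",
    "tilt_dose_series",
    "NO_LIMIT",
]

#: sentinel for "no resolution limit" (dz = 0); never used in arithmetic
NO_LIMIT = "no limit"


def electron_wavelength(kv: float) -> float:
    """Relativistic electron wavelength in Å for an accelerating voltage in kV.

    lambda = 12.2639 / sqrt(V * (1 + 0.97845e-6 * V)), V in volts.
    """
    if kv <= 0:
        raise ValueError("voltage must be positive")
    V = kv * 1000.0
    return 12.2639 / math.sqrt(V * (1.0 + 0.97845e-6 * V))


@dataclass
class CtfParams:
    """Microscope parameters for CTF phase calculations.

    Defocus is underfocus-positive.  The default is a 300 kV instrument;
    the wavelength is always derived from the voltage.
    """

    kv: float = 300.0
    cs_mm: float = 2.7
    defocus_um: float = 1.5
    phase_threshold: float = math.pi / 2.0

    def __post_init__(self) -> None:
        if self.defocus_um <= 0:
            raise ValueError("defocus must be positive (underfocus)")

    @property
    def wavelength(self) -> float:
        return electron_wavelength(self.kv)


def ctf_phase(s: float, defocus_A: float, params: CtfParams) -> float:
    """CTF phase gamma(s) in radians at spatial frequency s (1/Å).

    gamma = -pi * lambda * dz * s^2 + (pi/2) * Cs * lambda^3 * s^4,
    underfocus positive.  Only phase differences enter the resolution
    criterion, so the sign convention is internal.
    """
    if s < 0:
        raise ValueError("spatial frequency must be >= 0")
    lam = params.wavelength
    cs = params.cs_mm * 1e7  # mm -> Å
    return -math.pi * lam * defocus_A * s**2 + 0.5 * math.pi * cs * lam**3 * s**4


def defocus_error_resolution_limit(dz_A: float, params: CtfParams | None = None):
    """Resolution limit (Å) where two CTFs differing by dz dephase by 90°.

    Solves pi * lambda * dz * s^2 = phase_threshold for s and returns
    d = 1/s; with the default pi/2 threshold, d = sqrt(2 * lambda * dz).
    Returns :data:`NO_LIMIT` for dz = 0.
    """
    if dz_A < 0:
        raise ValueError("defocus error must be >= 0")
    params = params or CtfParams()
    if dz_A == 0:
        return NO_LIMIT
    return math.sqrt(math.pi * params.wavelength * dz_A / params.phase_threshold)


def tilt_defocus_offset(field_width_A: float, tilt_deg: float) -> float:
    """Worst-case defocus deviation (Å) across a tilted field of view.

    The particle at the field edge sits (width/2) * tan(tilt) above or
    below the centre defocus.
    """
    if field_width_A <= 0:
        raise ValueError("field width must be positive")
    if not (0.0 <= tilt_deg < 90.0):
        raise ValueError("tilt must be in [0, 90)")
    return 0.5 * field_width_A * math.tan(math.radians(tilt_deg))


def bilayer_defocus_offset(thickness_nm: float) -> float:
    """Defocus deviation (nm) of each layer from the midway estimate.

    Whole-image defocus estimation on a double-layered area lands halfway
    between the layers, so each layer is off by thickness/2.
    """
    if thickness_nm < 0:
        raise ValueError("thickness must be >= 0")
    return thickness_nm / 2.0


def duplicate_defocus_candidates(
    midway_um: float, thickness_nm: float
) -> tuple[float, float]:
    """Duplicate-defocus rescue pair (µm) for a double-layered area.

    Each particle is duplicated and CTF-corrected once with
    (midway + thickness/2) and once with (midway - thickness/2); the copy
    with the lower high-frequency cross-correlation is discarded later.
    Returned ordered (higher, lower); their midpoint is the midway value.
    """
    if thickness_nm < 0:
        raise ValueError("thickness must be >= 0")
    half_um = thickness_nm / 2.0 / 1000.0
    return (midway_um + half_um, midway_um - half_um)


def tilt_dose_series(
    dose0: float, angles_deg: list[float]
) -> tuple[list[float], float]:
    """Per-tilt doses (e-/Å^2) under the cosine scheme, plus the total.

    dose(theta) = dose0 / cos(theta), compensating the longer path length
    at high tilt.
    """
    doses = []
    for a in angles_deg:
        if abs(a) >= 90.0:
            raise ValueError("tilt angles must satisfy |angle| < 90")
        doses.append(dose0 / math.cos(math.radians(a)))
    return doses, sum(doses)
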