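"""Tomographic density volumes.

A :class:`Volume` is a 3D density grid indexed ``(z, y, x)`` with the z axis
along the electron beam.  All physical coordinates used by the analysis
modules are in nanometres; the voxel size stored in the MRC header (in
ångströms) is the only place where the voxel/physical conversion happens.
Voxel centres sit at ``(index + 0.5) * voxel size``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import gemmi
import numpy as np

__all__ = ["Volume", "read_volume", "write_volume"]


@dataclass
class Volume:
    """3D density grid with voxel size.

    Parameters
    ----------
    data:
        Array of shape ``(nz, ny, nx)``; float32 preferred.
    voxel_size:
        Edge length of one (cubic) voxel in ångströms.
    """

    data: np.ndarray
    voxel_size: float
    path: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {self.data.shape}")
        if not self.voxel_size > 0:
            raise ValueError(f"voxel size must be positive, got {self.voxel_size}")

    @property
    def voxel_nm(self) -> float:
        """Voxel edge length in nanometres."""
        return self.voxel_size / 10.0

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def axis_coords_nm(self, axis: int) -> np.ndarray:
        """Physical coordinates (nm) of voxel centres along one axis (0=z,1=y,2=x)."""
        n = self.data.shape[axis]
        return (np.arange(n) + 0.5) * self.voxel_nm

    def extent_nm(self) -> tuple[float, float, float]:
        """Physical size (nm) of the volume along (z, y, x)."""
        nz, ny, nx = self.data.shape
        return (nz * self.voxel_nm, ny * self.voxel_nm, nx * self.voxel_nm)

    def binned(self, factor: int) -> "Volume":
        """Block-average by an integer factor along every axis.

        Trailing voxels that do not fill a complete block are dropped, the
        same convention used by tomogram binning utilities.
        """
        if factor < 1:
            raise ValueError("bin factor must be >= 1")
        if factor == 1:
            return self
        nz, ny, nx = self.data.shape
        mz, my, mx = nz // factor, ny // factor, nx // factor
        if min(mz, my, mx) < 1:
            raise ValueError(f"volume {self.data.shape} too small to bin by {factor}")
        d = self.data[: mz * factor, : my * factor, : mx * factor]
        d = d.reshape(mz, factor, my, factor, mx, factor).mean(axis=(1, 3, 5))
        return Volume(d.astype(np.float32), self.voxel_size * factor, path=self.path)


def read_volume(path: str, voxel_size: float | None = None) -> Volume:
    """Read an MRC2014 / CCP4 map into a :class:`Volume`.

    The voxel size is taken from the header (cell / sampling).  A header
    without a usable voxel size falls back to *voxel_size* with a warning;
    if neither is available this is an error.
    """
    try:
        m = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError, OSError) as exc:
        raise ValueError(f"cannot read MRC volume {path!r}: {exc}") from exc
    m.setup(float("nan"))
    arr = np.array(m.grid, copy=True)  # gemmi grids are (nx, ny, nz)
    data = np.ascontiguousarray(arr.transpose(2, 1, 0)).astype(np.float32)
    sp = m.grid.spacing
    apix = float(sp[0])
    if not np.isfinite(apix) or apix <= 0 or not np.allclose(sp, apix, rtol=1e-3):
        if voxel_size is None:
            raise ValueError(
                f"{path!r} has no usable voxel size in its header and no fallback was given"
            )
        warnings.warn(
            f"{path!r}: header voxel size unusable ({sp}); using {voxel_size} A/px",
            stacklevel=2,
        )
        apix = float(voxel_size)
    return Volume(data, apix, path=str(path))


def write_volume(vol: Volume, path: str) -> None:
    """Write a :class:`Volume` as an MRC2014 map with voxel size in the header."""
    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(
        np.ascontiguousarray(vol.data.astype(np.float32).transpose(2, 1, 0))
    )
    nz, ny, nx = vol.data.shape
    a = vol.voxel_size
    m.grid.set_unit_cell(gemmi.UnitCell(nx * a, ny * a, nz * a, 90.0, 90.0, 90.0))
    m.grid.spacegroup = gemmi.SpaceGroup("P1")
    m.update_ccp4_header()
    m.write_ccp4_map(str(path))
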