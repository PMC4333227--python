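"""Voxel grids and the mask linearization shared by every stage of the pipeline.

A :class:`VoxelGrid` couples a 3-D image geometry (dims + affine) with a boolean
brain mask.  All pattern matrices in this package store one column per in-mask
voxel; the column order is fixed by :meth:`VoxelGrid.linear_indices`: in-mask
voxels sorted by the flat index ``f = x + nx*(y + ny*z)``, i.e. a raster scan
with x fastest and z slowest, 0-based.  Every map, beta matrix and NIfTI export
uses this single linearization, so column ``j`` always denotes the same voxel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VoxelGrid", "ellipsoid_grid"]


@dataclass(frozen=True, eq=False)
class VoxelGrid:
    """3-D grid geometry plus a boolean analysis mask.

    Parameters
    ----------
    dims : tuple of int
        Voxel counts ``(nx, ny, nz)``.
    affine : ndarray, shape (4, 4)
        Voxel-index -> mm transform (NIfTI convention).
    mask : ndarray of bool, shape ``dims``
        True for voxels included in the analysis.
    """

    dims: tuple
    affine: np.ndarray
    mask: np.ndarray

    def __post_init__(self):
        dims = tuple(int(d) for d in self.dims)
        object.__setattr__(self, "dims", dims)
        if len(dims) != 3 or any(d < 1 for d in dims):
            raise ValueError(f"dims must be three positive ints, got {dims}")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        object.__setattr__(self, "affine", affine)
        mask = np.asarray(self.mask, dtype=bool)
        if mask.shape != dims:
            raise ValueError(f"mask shape {mask.shape} != dims {dims}")
        object.__setattr__(self, "mask", mask)
        # flat index f = x + nx*(y + ny*z): Fortran raveling of an (nx,ny,nz) array
        object.__setattr__(
            self, "_lin", np.flatnonzero(np.ravel(mask, order="F"))
        )

    @property
    def p(self) -> int:
        """Number of in-mask voxels (pattern-matrix columns)."""
        return int(self._lin.size)

    @property
    def linear_indices(self) -> np.ndarray:
        """Sorted flat indices (x fastest) of the in-mask voxels."""
        return self._lin

    def coords(self) -> np.ndarray:
        """(p, 3) integer ``(x, y, z)`` coordinates, one row per column."""
        nx, ny, _ = self.dims
        f = self._lin
        x = f % nx
        y = (f // nx) % ny
        z = f // (nx * ny)
        return np.stack([x, y, z], axis=1)

    def to_volume(self, values, fill=0.0) -> np.ndarray:
        """Scatter a length-p vector into a 3-D volume (outside-mask = fill)."""
        values = np.asarray(values)
        if values.shape != (self.p,):
            raise ValueError(f"expected length-{self.p} vector, got {values.shape}")
        flat = np.full(int(np.prod(self.dims)), fill, dtype=values.dtype)
        flat[self._lin] = values
        return flat.reshape(self.dims, order="F")

    def from_volume(self, volume) -> np.ndarray:
        """Gather the in-mask voxels of a 3-D volume into a length-p vector."""
        volume = np.asarray(volume)
        if volume.shape != self.dims:
            raise ValueError(f"volume shape {volume.shape} != dims {self.dims}")
        return volume.reshape(-1, order="F")[self._lin]

    def voxel_to_mm(self, ijk) -> np.ndarray:
        """Apply the affine to integer voxel coordinates (rows of (x, y, z))."""
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        hom = np.hstack([ijk, np.ones((ijk.shape[0], 1))])
        return (hom @ self.affine.T)[:, :3]


def ellipsoid_grid(dims=(20, 20, 10), voxel_mm=(1.7, 1.7, 2.0)) -> VoxelGrid:
    """Build a grid whose mask is the inscribed ellipsoid of the box.

    The default 20 x 20 x 10 box yields ~2000 in-mask voxels, a deliberately
    small stand-in for a temporal-lobe mask; real masks can be loaded from
    NIfTI instead.  The affine is diagonal with the acquisition voxel size
    (1.7 x 1.7 x 2 mm default) and origin at the volume center.
    """
    dims = tuple(int(d) for d in dims)
    semi = np.array([(d - 1) / 2.0 for d in dims])
    center = semi.copy()
    x, y, z = np.meshgrid(*[np.arange(d) for d in dims], indexing="ij")
    r2 = (
        ((x - center[0]) / max(semi[0], 0.5)) ** 2
        + ((y - center[1]) / max(semi[1], 0.5)) ** 2
        + ((z - center[2]) / max(semi[2], 0.5)) ** 2
    )
    mask = r2 <= 1.0
    affine = np.diag(list(voxel_mm) + [1.0])
    affine[:3, 3] = -center * np.asarray(voxel_mm)
    return VoxelGrid(dims=dims, affine=affine, mask=mask)
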