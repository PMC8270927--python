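"""Axis-aligned volumetric grids and resampling between them.

World coordinates are millimetres.  Array axis order is fixed as
``(x, y, slice)``; the slice axis is the vessel axis, so ``data[:, :, k]``
is one axial slice.  Grids carry no rotation of their own — all inter-frame
rotation lives in :class:`plaquekit.register.SimilarityTransform`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = ["GridGeometry", "ImageVolume", "resample"]


@dataclass(frozen=True)
class GridGeometry:
    """Shape, voxel size and world origin of a regular 3-D grid.

    Parameters
    ----------
    shape : tuple of int
        Voxels per axis, ``(nx, ny, nslice)``.
    voxel_size : tuple of float
        Millimetres per voxel along each axis; all strictly positive.
    origin_offset : tuple of float
        World position (mm) of the centre of voxel ``(0, 0, 0)``.
    """

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    origin_offset: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or len(self.voxel_size) != 3:
            raise ValueError("GridGeometry is strictly 3-D")
        if any(n < 1 for n in self.shape):
            raise ValueError(f"non-positive shape {self.shape}")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be positive, got {self.voxel_size}")

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> world (mm) affine (diagonal, RAS-like)."""
        a = np.eye(4)
        a[:3, :3] = np.diag(self.voxel_size)
        a[:3, 3] = self.origin_offset
        return a

    @property
    def fov_mm(self) -> np.ndarray:
        """Physical extent per axis in mm."""
        return np.asarray(self.shape) * np.asarray(self.voxel_size)

    @property
    def center_world(self) -> np.ndarray:
        """World coordinate of the grid centre."""
        return self.index_to_world((np.asarray(self.shape) - 1) / 2.0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size))

    def index_to_world(self, idx) -> np.ndarray:
        arr = np.asarray(idx, dtype=float)
        out = np.atleast_2d(arr) * np.asarray(self.voxel_size) + np.asarray(
            self.origin_offset
        )
        return out[0] if arr.ndim == 1 else out

    def world_to_index(self, xyz) -> np.ndarray:
        arr = np.asarray(xyz, dtype=float)
        out = (np.atleast_2d(arr) - np.asarray(self.origin_offset)) / np.asarray(
            self.voxel_size
        )
        return out[0] if arr.ndim == 1 else out

    def slice_centers(self) -> np.ndarray:
        """World z (mm) of every slice centre along the vessel axis."""
        return (
            np.arange(self.shape[2]) * self.voxel_size[2] + self.origin_offset[2]
        )

    def contains_world(self, xyz) -> np.ndarray:
        """True where a world point falls inside the grid's voxel lattice."""
        idx = np.atleast_2d(self.world_to_index(xyz))
        lo = idx >= -0.5
        hi = idx <= np.asarray(self.shape) - 0.5
        return np.all(lo & hi, axis=1)


@dataclass
class ImageVolume:
    """A scalar volume bound to its grid geometry."""

    data: np.ndarray
    grid: GridGeometry
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.shape != tuple(self.grid.shape):
            raise ValueError(
                f"data shape {self.data.shape} != grid shape {self.grid.shape}"
            )


def _compose_index_map(
    source: GridGeometry, target: GridGeometry, world_map: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray]:
    """Matrix/offset taking target voxel indices to source voxel indices.

    ``world_map`` is a 4x4 affine mapping target-world -> source-world
    (identity when None).
    """
    m = np.eye(4) if world_map is None else np.asarray(world_map, dtype=float)
    src_inv = np.eye(4)
    src_inv[:3, :3] = np.diag(1.0 / np.asarray(source.voxel_size))
    src_inv[:3, 3] = -np.asarray(source.origin_offset) / np.asarray(source.voxel_size)
    full = src_inv @ m @ target.affine
    return full[:3, :3], full[:3, 3]


def resample(
    volume: ImageVolume,
    target: GridGeometry,
    world_map: np.ndarray | None = None,
    order: int = 1,
    cval: float = np.nan,
) -> ImageVolume:
    """Resample ``volume`` onto ``target``.

    ``world_map`` maps target-world coordinates into the source's world frame
    (e.g. ``SimilarityTransform.matrix`` when the source lives in a different
    session frame).  ``order=0`` gives nearest-neighbour (use for masks),
    ``order=1`` trilinear.  Points outside the source grid get ``cval``.
    """
    mat, off = _compose_index_map(volume.grid, target, world_map)
    data = ndimage.affine_transform(
        np.asarray(volume.data, dtype=float),
        mat,
        offset=off,
        output_shape=tuple(target.shape),
        order=order,
        mode="constant",
        cval=cval,
    )
    return ImageVolume(data=data, grid=target)
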