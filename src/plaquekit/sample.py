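"""Sampling composition maps under a plaque mask.

Before statistics, every in-mask voxel of a quantitative map is replaced by
the average of its immediate neighbours that lie within the mask (the voxel
itself included by default); only slice averages and the whole-mask average
then enter the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import GridGeometry

__all__ = [
    "PlaqueMask",
    "neighborhood_average",
    "slice_means",
    "whole_mask_mean",
]


@dataclass
class PlaqueMask:
    """Binary region of interest on an anatomical grid.

    The mask delineates the thickened vessel wall (plaque: a luminal
    protrusion of the wall of at least 1.5 mm radial thickness), sliced
    along the vessel axis.
    """

    voxels: np.ndarray
    grid: GridGeometry
    allow_empty: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if self.voxels.shape != tuple(self.grid.shape):
            raise ValueError("mask is not on its grid")
        if not self.allow_empty and not self.voxels.any():
            raise ValueError("empty plaque mask")

    @property
    def slice_ids(self) -> np.ndarray:
        """Indices along the vessel axis with at least one mask voxel."""
        return np.flatnonzero(self.voxels.any(axis=(0, 1)))

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())


_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def neighborhood_average(
    volume: np.ndarray,
    mask: PlaqueMask,
    connectivity: int = 26,
    include_self: bool = True,
) -> np.ndarray:
    """Masked neighbour averaging of a quantitative map.

    Each in-mask voxel becomes the mean of the map over its neighbours that
    are themselves in the mask (26-connected by default, self included).
    An isolated voxel with no in-mask neighbours keeps its own value.
    Out-of-mask voxels are NaN in the output.
    """
    vol = np.asarray(volume, dtype=float)
    if vol.shape != tuple(mask.grid.shape):
        raise ValueError("map and mask are on different grids")
    if connectivity not in _STRUCTS:
        raise ValueError("connectivity must be one of 6, 18, 26")
    kernel = _STRUCTS[connectivity].astype(float)
    if not include_self:
        kernel[1, 1, 1] = 0.0
    m = mask.voxels.astype(float)
    vals = np.where(mask.voxels, vol, 0.0)
    sums = ndimage.correlate(vals, kernel, mode="constant", cval=0.0)
    counts = ndimage.correlate(m, kernel, mode="constant", cval=0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        avg = sums / counts
    avg = np.where(counts > 0, avg, vol)  # isolated voxel: own value
    return np.where(mask.voxels, avg, np.nan)


def slice_means(volume: np.ndarray, mask: PlaqueMask) -> pd.Series:
    """Unweighted in-mask mean per slice along the vessel axis.

    Slices without mask voxels are absent from the output.  NaN map values
    (e.g. invalid fit voxels) are ignored.
    """
    vol = np.asarray(volume, dtype=float)
    if vol.shape != tuple(mask.grid.shape):
        raise ValueError("map and mask are on different grids")
    out = {}
    for k in mask.slice_ids:
        vals = vol[:, :, k][mask.voxels[:, :, k]]
        vals = vals[np.isfinite(vals)]
        if vals.size:
            out[int(k)] = float(vals.mean())
    s = pd.Series(out, name="slice_mean")
    s.index.name = "slice_id"
    return s


def whole_mask_mean(
    volume: np.ndarray, mask: PlaqueMask, slice_weighted: bool = False
) -> float:
    """In-mask mean of a map over the whole plaque.

    Voxel-weighted by default (a plain mean over every mask voxel); the
    slice-weighted alternative — mean of per-slice means — is exposed
    because a per-slice read of the aggregation is equally defensible.
    """
    if slice_weighted:
        return float(slice_means(volume, mask).mean())
    vol = np.asarray(volume, dtype=float)
    if vol.shape != tuple(mask.grid.shape):
        raise ValueError("map and mask are on different grids")
    vals = vol[mask.voxels]
    vals = vals[np.isfinite(vals)]
    if not vals.size:
        raise ValueError("whole-mask mean undefined: no finite in-mask values")
    return float(vals.mean())
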