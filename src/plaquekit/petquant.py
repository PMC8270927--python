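"""18F-FDG PET quantification: SUV maps, plaque SUV statistics and TBR.

SUV normalizes tissue activity concentration by injected dose per body
weight (unit tissue density, 1 g/mL); with activity in kBq/mL, dose in MBq
and weight in kg the factors cancel to

    SUV = activity * body_weight / injected_dose.

The target-to-blood-pool ratio divides the whole-plaque SUV_mean by a
venous blood-pool SUV_mean taken as the average of exactly six point
samples.  The whole-plaque SUV_mean is formed slice-first: mean SUV per
plaque slice ROI, then the unweighted mean over slices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import GridGeometry, ImageVolume
from .sample import PlaqueMask

__all__ = ["PETStudy", "SUVResult", "suv_map", "plaque_suv", "blood_pool_suv", "tbr"]


@dataclass
class PETStudy:
    """Activity-concentration volume with dosing metadata."""

    activity: np.ndarray  # kBq/mL
    grid: GridGeometry
    injected_dose_mbq: float
    body_weight_kg: float
    uptake_time_min: float = 90.0  # metadata only; decay correction is the scanner's
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.activity = np.asarray(self.activity, dtype=float)
        if self.activity.shape != tuple(self.grid.shape):
            raise ValueError("activity volume is not on its grid")
        if not self.injected_dose_mbq > 0:
            raise ValueError("injected dose must be positive")
        if not self.body_weight_kg > 0:
            raise ValueError("body weight must be positive")
        if np.nanmin(self.activity) < 0:
            raise ValueError("activity must be non-negative")


@dataclass
class SUVResult:
    """Per-slice and whole-plaque SUV statistics plus blood pool and TBR."""

    per_slice: pd.DataFrame  # index slice_id; columns suv_mean, suv_max, n_voxels
    suv_mean_plaque: float
    suv_max_plaque: float
    suv_mean_blood: float | None = None
    tbr: float | None = None


def suv_map(study: PETStudy) -> ImageVolume:
    """Standardized-uptake-value volume (dimensionless)."""
    suv = study.activity * study.body_weight_kg / study.injected_dose_mbq
    return ImageVolume(suv, study.grid, meta={"kind": "SUV"})


def plaque_suv(
    suv: ImageVolume, mask: PlaqueMask, slice_first: bool = True
) -> SUVResult:
    """Per-slice and whole-plaque SUV statistics under the mask.

    The whole-plaque SUV_mean is the unweighted mean of per-slice ROI means
    (``slice_first=True``, the reference procedure); ``slice_first=False``
    pools all mask voxels instead.  SUV_max is the maximum over the whole
    mask either way.  The mask must already live on the PET grid.
    """
    if tuple(mask.grid.shape) != tuple(suv.grid.shape):
        raise ValueError("mask must be resampled onto the PET grid first")
    if not mask.voxels.any():
        raise ValueError("empty plaque mask on the PET grid")
    rows = []
    for k in mask.slice_ids:
        vals = np.asarray(suv.data)[:, :, k][mask.voxels[:, :, k]]
        vals = vals[np.isfinite(vals)]
        if vals.size:
            rows.append(
                {
                    "slice_id": int(k),
                    "suv_mean": float(vals.mean()),
                    "suv_max": float(vals.max()),
                    "n_voxels": int(vals.size),
                }
            )
    per_slice = pd.DataFrame(rows).set_index("slice_id")
    if slice_first:
        whole_mean = float(per_slice["suv_mean"].mean())
    else:
        allv = np.asarray(suv.data)[mask.voxels]
        whole_mean = float(allv[np.isfinite(allv)].mean())
    whole_max = float(per_slice["suv_max"].max())
    return SUVResult(
        per_slice=per_slice, suv_mean_plaque=whole_mean, suv_max_plaque=whole_max
    )


def blood_pool_suv(
    suv: ImageVolume, points_world_mm: np.ndarray, radius_mm: float = 0.0
) -> float:
    """Venous blood-pool SUV_mean from exactly six sample points.

    ``points_world_mm`` is a (6, 3) array of world coordinates; each sample
    is a nearest-voxel lookup (``radius_mm > 0`` averages over a small
    sphere instead).  Points outside the volume are rejected.
    """
    pts = np.atleast_2d(np.asarray(points_world_mm, dtype=float))
    if pts.shape != (6, 3):
        raise ValueError(f"exactly 6 blood-pool points required, got {pts.shape}")
    inside = suv.grid.contains_world(pts)
    if not inside.all():
        raise ValueError("blood-pool point(s) outside the PET volume")
    data = np.asarray(suv.data, dtype=float)
    samples = []
    for p in pts:
        idx = np.rint(suv.grid.world_to_index(p)).astype(int)
        idx = np.clip(idx, 0, np.asarray(suv.grid.shape) - 1)
        if radius_mm > 0:
            ii = np.indices(data.shape).reshape(3, -1).T
            d = np.linalg.norm(
                (ii - idx) * np.asarray(suv.grid.voxel_size), axis=1
            )
            sel = data.reshape(-1)[d <= radius_mm]
            samples.append(float(sel.mean()))
        else:
            samples.append(float(data[tuple(idx)]))
    return float(np.mean(samples))


def tbr(suv_mean_plaque: float, suv_mean_blood: float) -> float:
    """Target-to-blood-pool ratio: plaque SUV_mean / blood-pool SUV_mean."""
    if not suv_mean_blood > 0:
        raise ValueError("blood-pool SUV_mean must be positive")
    return float(suv_mean_plaque) / float(suv_mean_blood)
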