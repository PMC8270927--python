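"""NIfTI / JSON / CSV round-tripping for pipeline artifacts.

Volumes travel as NIfTI-1 with the grid's diagonal affine; acquisition
metadata (echo times, dose, weight) as JSON sidecars; ROI tables as CSV;
similarity transforms as JSON (translation mm, rotation deg, scale,
centre mm).
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .dixon import DixonSeries
from .grid import GridGeometry, ImageVolume
from .petquant import PETStudy
from .register import SimilarityTransform

__all__ = [
    "save_volume",
    "load_volume",
    "save_dixon_series",
    "load_dixon_series",
    "save_pet_study",
    "load_pet_study",
    "save_transform",
    "load_transform",
]


def save_volume(vol: ImageVolume, path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float64), vol.grid.affine)
    img.header.set_zooms(vol.grid.voxel_size)
    nib.save(img, path)
    return path


def load_volume(path) -> ImageVolume:
    img = nib.load(str(path))
    aff = img.affine
    if not np.allclose(aff[:3, :3], np.diag(np.diag(aff[:3, :3]))):
        raise ValueError("only axis-aligned (diagonal-affine) NIfTI volumes supported")
    grid = GridGeometry(
        tuple(int(s) for s in img.shape[:3]),
        tuple(float(v) for v in np.diag(aff[:3, :3])),
        tuple(float(v) for v in aff[:3, 3]),
    )
    return ImageVolume(np.asarray(img.dataobj, dtype=float), grid)


def save_dixon_series(series: DixonSeries, outdir, stem: str = "echo") -> Path:
    """Write echo volumes as ``<stem>_1.nii ...`` plus a JSON sidecar of TEs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    names = []
    for i, (te, vol) in enumerate(series.echoes, start=1):
        name = f"{stem}_{i}.nii"
        save_volume(ImageVolume(vol, series.grid), outdir / name)
        names.append(name)
    sidecar = {"echo_times_ms": [te for te, _ in series.echoes], "volumes": names}
    (outdir / f"{stem}.json").write_text(json.dumps(sidecar, indent=2))
    return outdir / f"{stem}.json"


def load_dixon_series(sidecar_path) -> DixonSeries:
    sidecar_path = Path(sidecar_path)
    meta = json.loads(sidecar_path.read_text())
    echoes = []
    grid = None
    for te, name in zip(meta["echo_times_ms"], meta["volumes"]):
        vol = load_volume(sidecar_path.parent / name)
        grid = grid or vol.grid
        echoes.append((float(te), vol.data))
    return DixonSeries(echoes=echoes, grid=grid)


def save_pet_study(study: PETStudy, outdir, stem: str = "pet") -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    save_volume(ImageVolume(study.activity, study.grid), outdir / f"{stem}.nii")
    sidecar = {
        "injected_dose_mbq": study.injected_dose_mbq,
        "body_weight_kg": study.body_weight_kg,
        "uptake_time_min": study.uptake_time_min,
        "volume": f"{stem}.nii",
    }
    (outdir / f"{stem}.json").write_text(json.dumps(sidecar, indent=2))
    return outdir / f"{stem}.json"


def load_pet_study(sidecar_path) -> PETStudy:
    sidecar_path = Path(sidecar_path)
    meta = json.loads(sidecar_path.read_text())
    vol = load_volume(sidecar_path.parent / meta["volume"])
    return PETStudy(
        activity=vol.data,
        grid=vol.grid,
        injected_dose_mbq=float(meta["injected_dose_mbq"]),
        body_weight_kg=float(meta["body_weight_kg"]),
        uptake_time_min=float(meta.get("uptake_time_min", 90.0)),
    )


def save_transform(tfm: SimilarityTransform, path) -> Path:
    path = Path(path)
    path.write_text(
        json.dumps(
            {
                "translation_mm": list(tfm.translation),
                "rotation_deg": list(tfm.rotation_deg),
                "scale": tfm.scale,
                "center_mm": list(tfm.center),
            },
            indent=2,
        )
    )
    return path


def load_transform(path) -> SimilarityTransform:
    d = json.loads(Path(path).read_text())
    return SimilarityTransform(
        translation=tuple(d["translation_mm"]),
        rotation_deg=tuple(d["rotation_deg"]),
        scale=float(d["scale"]),
        center=tuple(d.get("center_mm", (0.0, 0.0, 0.0))),
    )
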