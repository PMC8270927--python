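"""Digital carotid-plaque phantoms with known ground truth.

The phantom is a straight vessel along the slice axis: a low-signal lumen
(inflowing blood is suppressed in the MR acquisitions), a vessel wall of
uniform baseline thickness, and an eccentric wall thickening — the plaque —
over an angular sector and a contiguous slice range.  Inside the plaque sit
a lipid-rich core (elevated fat fraction, the lipid-rich-necrotic-core
surrogate) and a hemorrhagic region (elevated R2*, the intraplaque-
hemorrhage surrogate).  The carotid bifurcation is modelled as a marked
slice index used as the landmark for cross-session slice alignment.

Every downstream input of the analysis chain can be rendered from one
truth object: the 4-echo Dixon magnitude series, T1-weighted volumes on
the stand-alone and PET/MR session grids (the latter displaced by a
session transform the pipeline must recover), and the PET activity volume
blurred to the scanner's effective resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import dixon
from .grid import GridGeometry, ImageVolume, resample
from .register import SimilarityTransform
from .sample import PlaqueMask

__all__ = [
    "PhantomConfig",
    "PhantomTruth",
    "T1WVolume",
    "make_phantom",
    "render_dixon",
    "render_t1w",
    "render_pet",
    "blood_sample_points",
]

# compartment labels
BACKGROUND, LUMEN, WALL, PLAQUE = 0, 1, 2, 3

#: acquisition grids: Dixon, stand-alone T1W, PET/MR-session T1W, PET
DIXON_VOXEL = (0.6, 0.6, 0.7)
T1W_STANDALONE_VOXEL = (0.50, 0.50, 1.75)
T1W_PETMR_VOXEL = (0.31, 0.31, 2.5)
PET_VOXEL = (1.2, 1.2, 2.78)


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, composition and dosing of the digital plaque.

    Lengths in mm, angles in degrees, R2* in s^-1, activity in kBq/mL.
    Defaults give a plaque whose wall protrudes 3 mm (the clinical plaque
    definition requires >= 1.5 mm), a lipid core at fat fraction 0.4 and a
    hemorrhagic focus at R2* 90 s^-1, with a venous blood activity placing
    blood SUV near 1.3 under 3 MBq/kg dosing at 75 kg.
    """

    grid: GridGeometry = GridGeometry((40, 40, 36), DIXON_VOXEL)
    lumen_radius: float = 2.5
    wall_thickness: float = 1.0
    plaque_protrusion: float = 3.0  # extra wall thickness in the plaque sector
    plaque_theta0_deg: float = 20.0
    plaque_extent_deg: float = 140.0
    plaque_slice_range: tuple[int, int] = (10, 28)  # half-open, vessel axis
    bifurcation_slice: int = 10
    # composition (fat fraction as a fraction in [0, 1])
    lipid_core_ff: float = 0.4
    hemorrhage_r2star: float = 90.0
    wall_ff: float = 0.05
    wall_r2star: float = 40.0
    background_ff: float = 0.10
    background_r2star: float = 30.0
    tissue_signal: float = 1.0  # proton-signal density, arbitrary units
    background_signal: float = 0.5
    lumen_signal: float = 0.1  # blood-suppressed lumen
    # slice-to-slice heterogeneity (SD of a smooth seeded field)
    ff_jitter_sd: float = 0.04
    r2star_jitter_sd: float = 6.0
    activity_jitter_sd: float = 0.8
    # tracer and dosing
    blood_activity: float = 3.9  # kBq/mL -> blood SUV ~ 1.3 at 75 kg, 3 MBq/kg
    plaque_activity: float = 6.0
    background_activity: float = 1.0
    body_weight: float = 75.0
    dose_per_kg: float = 3.0  # MBq/kg
    # PET/MR session frame misalignment, drawn per seed within these bounds
    session_max_translation: float = 3.0
    session_max_rotation_deg: float = 3.0
    session_scale_range: tuple[float, float] = (0.98, 1.02)


@dataclass
class PhantomTruth:
    """Ground-truth maps and metadata of one synthetic subject."""

    water_map: np.ndarray
    fat_map: np.ndarray
    r2star_map: np.ndarray
    activity_map: np.ndarray
    plaque_mask_true: np.ndarray
    compartments: np.ndarray
    session_transform_true: SimilarityTransform
    grid: GridGeometry
    blood_activity: float
    body_weight: float
    injected_dose: float
    bifurcation_slice: int
    config: PhantomConfig
    seed: int
    degenerate: bool = False  # zero-extent plaque

    @property
    def fat_fraction_map(self) -> np.ndarray:
        total = self.water_map + self.fat_map
        with np.errstate(invalid="ignore", divide="ignore"):
            ff = self.fat_map / total
        return np.where(total > 0, ff, np.nan)

    def plaque_mask(self) -> PlaqueMask:
        return PlaqueMask(self.plaque_mask_true, self.grid, allow_empty=self.degenerate)


@dataclass
class T1WVolume(ImageVolume):
    """Anatomical T1-weighted volume with its bifurcation landmark slice."""

    landmark_slice: int = 0


def _smooth_field(shape, sd, rng, sigma_vox=2.0):
    """Seeded smooth zero-mean perturbation field with SD ~ ``sd``."""
    if sd == 0:
        return np.zeros(shape)
    noise = rng.standard_normal(shape)
    sm = ndimage.gaussian_filter(noise, sigma_vox)
    s = sm.std()
    return sm * (sd / s) if s > 0 else sm


def make_phantom(config: PhantomConfig | None = None, seed: int = 0) -> PhantomTruth:
    """Build the ground-truth maps for one synthetic subject.

    Deterministic for a fixed (config, seed).  The plaque compartment is
    guaranteed to contain at least one voxel at the configured lipid-core
    fat fraction and one at the configured hemorrhage R2*.  A zero-extent
    plaque yields an empty mask and a truth flagged degenerate.
    """
    cfg = config or PhantomConfig()
    grid = cfg.grid
    outer = cfg.lumen_radius + cfg.wall_thickness + cfg.plaque_protrusion
    if 2 * outer > min(grid.fov_mm[0], grid.fov_mm[1]):
        raise ValueError(
            f"vessel (outer radius {outer:.1f} mm) does not fit inside the "
            f"{grid.fov_mm[0]:.1f} x {grid.fov_mm[1]:.1f} mm field of view"
        )
    if cfg.plaque_protrusion > 0 and cfg.plaque_protrusion < 1.5:
        raise ValueError(
            "plaque wall protrusion must be >= 1.5 mm (plaque definition) or 0"
        )
    rng = np.random.default_rng(seed)

    ix, iy = np.indices(grid.shape[:2])
    cx, cy = (np.asarray(grid.shape[:2]) - 1) / 2.0
    x = (ix - cx) * grid.voxel_size[0]
    y = (iy - cy) * grid.voxel_size[1]
    r = np.hypot(x, y)
    theta = np.degrees(np.arctan2(y, x)) % 360.0

    z0, z1 = cfg.plaque_slice_range
    t0 = cfg.plaque_theta0_deg % 360.0
    in_sector = ((theta - t0) % 360.0) <= cfg.plaque_extent_deg
    degenerate = cfg.plaque_extent_deg <= 0 or z1 <= z0 or cfg.plaque_protrusion <= 0

    comp = np.full(grid.shape, BACKGROUND, dtype=np.int8)
    comp[r <= cfg.lumen_radius + cfg.wall_thickness] = WALL
    comp[r <= cfg.lumen_radius] = LUMEN
    plaque = np.zeros(grid.shape, dtype=bool)
    if not degenerate:
        sector_wall = (
            in_sector
            & (r > cfg.lumen_radius)
            & (r <= cfg.lumen_radius + cfg.wall_thickness + cfg.plaque_protrusion)
        )
        plaque[:, :, z0:z1] = sector_wall[:, :, None]
        # only wall/extended-wall voxels, never lumen
        plaque &= comp != LUMEN
        comp[plaque] = PLAQUE

    ff = np.full(grid.shape, cfg.background_ff)
    r2s = np.full(grid.shape, cfg.background_r2star)
    signal = np.full(grid.shape, cfg.background_signal)
    for label, f_, r_, s_ in (
        (LUMEN, 0.0, 20.0, cfg.lumen_signal),
        (WALL, cfg.wall_ff, cfg.wall_r2star, cfg.tissue_signal),
        (PLAQUE, cfg.wall_ff, cfg.wall_r2star, cfg.tissue_signal),
    ):
        sel = comp == label
        ff[sel], r2s[sel], signal[sel] = f_, r_, s_

    activity = np.full(grid.shape, cfg.background_activity)
    activity[comp == LUMEN] = cfg.blood_activity

    if not degenerate:
        # lipid core: inner radial half of the sector, central plaque slices
        mid = (t0 + cfg.plaque_extent_deg / 2.0) % 360.0
        half = cfg.plaque_extent_deg / 2.0
        ang_off = (theta - mid + 180.0) % 360.0 - 180.0
        core2d = (
            in_sector
            & (np.abs(ang_off) <= half / 2.0)
            & (r <= cfg.lumen_radius + cfg.wall_thickness + cfg.plaque_protrusion / 2.0)
        )
        hem2d = in_sector & (ang_off > half / 2.0) & (
            r > cfg.lumen_radius + cfg.wall_thickness + cfg.plaque_protrusion / 2.0
        )
        zc0 = z0 + max(1, (z1 - z0) // 6)
        zc1 = z1 - max(1, (z1 - z0) // 6)
        core = np.zeros(grid.shape, dtype=bool)
        hem = np.zeros(grid.shape, dtype=bool)
        core[:, :, zc0:zc1] = core2d[:, :, None]
        hem[:, :, zc0:zc1] = hem2d[:, :, None]
        core &= plaque
        hem &= plaque
        # heterogeneity is one-sided so configured levels stay attained
        ff[core] = cfg.lipid_core_ff + np.abs(
            _smooth_field(grid.shape, cfg.ff_jitter_sd, rng)[core]
        )
        r2s[hem] = cfg.hemorrhage_r2star + np.abs(
            _smooth_field(grid.shape, cfg.r2star_jitter_sd, rng)[hem]
        )
        act_jit = _smooth_field(grid.shape, cfg.activity_jitter_sd, rng)
        activity[plaque] = np.maximum(cfg.plaque_activity + act_jit[plaque], 0.1)

    ff = np.clip(ff, 0.0, 0.5)
    r2s = np.clip(r2s, 0.0, dixon.R2STAR_MAX)
    water = (1.0 - ff) * signal
    fat = ff * signal

    # session transform: drawn per seed, unknown to the pipeline
    t = rng.uniform(-cfg.session_max_translation, cfg.session_max_translation, 3)
    rot = rng.uniform(-cfg.session_max_rotation_deg, cfg.session_max_rotation_deg, 3)
    sc = rng.uniform(*cfg.session_scale_range)
    session = SimilarityTransform(
        translation=tuple(t),
        rotation_deg=tuple(rot),
        scale=float(sc),
        center=tuple(grid.center_world),
    )

    return PhantomTruth(
        water_map=water,
        fat_map=fat,
        r2star_map=r2s,
        activity_map=activity,
        plaque_mask_true=plaque,
        compartments=comp,
        session_transform_true=session,
        grid=grid,
        blood_activity=cfg.blood_activity,
        body_weight=cfg.body_weight,
        injected_dose=cfg.dose_per_kg * cfg.body_weight,
        bifurcation_slice=cfg.bifurcation_slice,
        config=cfg,
        seed=seed,
        degenerate=degenerate,
    )


def render_dixon(
    truth: PhantomTruth,
    noise_sd: float = 0.0,
    seed: int = 0,
    tes_ms=dixon.DEFAULT_ECHO_TIMES_MS,
) -> dixon.DixonSeries:
    """Forward-render the 4-echo Dixon magnitude series.

    Noise is complex Gaussian on two quadrature channels before the
    magnitude (Rician), matching how magnitude MR data arise; ``noise_sd``
    is the per-channel SD in signal units and 0 gives the exact forward
    model.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    echoes = []
    for te in tes_ms:
        s = dixon.forward_signal(truth.water_map, truth.fat_map, truth.r2star_map, te)
        if noise_sd > 0:
            re = s + rng.normal(0.0, noise_sd, s.shape)
            im = rng.normal(0.0, noise_sd, s.shape)
            s = np.hypot(re, im)
        echoes.append((float(te), s))
    return dixon.DixonSeries(echoes=echoes, grid=truth.grid, meta={"seed": seed})


#: T1W contrast per compartment (arbitrary units)
_T1W_LEVELS = {BACKGROUND: 0.35, LUMEN: 0.10, WALL: 0.65, PLAQUE: 0.85}

#: SD of the smooth anatomical texture superimposed on the compartments.
#: Soft tissue is not uniform; texture that travels with the anatomy is
#: also what makes intensity-based registration well-posed far from the
#: vessel (a flat background rewards any transform that piles background
#: onto background).
_T1W_TEXTURE_SD = 0.06


def _t1w_contrast(truth: PhantomTruth) -> np.ndarray:
    out = np.empty(truth.grid.shape)
    for label, level in _T1W_LEVELS.items():
        out[truth.compartments == label] = level
    rng = np.random.default_rng(truth.seed + 7919)  # anatomy-fixed texture
    out = out + _smooth_field(truth.grid.shape, _T1W_TEXTURE_SD, rng, sigma_vox=1.5)
    return np.clip(out, 0.0, None)


def _session_grid(truth: PhantomTruth, voxel) -> GridGeometry:
    fov = truth.grid.fov_mm
    shape = tuple(int(max(1, np.floor(f / v))) for f, v in zip(fov, voxel))
    g = GridGeometry(shape, tuple(voxel))
    # centre the session grid on the phantom centre
    shift = truth.grid.center_world - g.center_world
    return GridGeometry(shape, tuple(voxel), tuple(shift))


def render_t1w(
    truth: PhantomTruth, session: str = "standalone", grid: GridGeometry | None = None
) -> T1WVolume:
    """Render an anatomical T1W volume for one scanner session.

    ``standalone`` resamples the phantom-frame contrast onto the
    0.50 x 0.50 x 1.75 mm grid; ``petmr`` onto the 0.31 x 0.31 x 2.5 mm grid
    *after* displacing the anatomy by the true session transform, so the
    two sessions are misaligned by exactly that transform.  A custom
    ``grid`` overrides the session default.
    """
    if session not in ("standalone", "petmr"):
        raise ValueError(f"unknown session {session!r} (use 'standalone' or 'petmr')")
    voxel = T1W_STANDALONE_VOXEL if session == "standalone" else T1W_PETMR_VOXEL
    g = grid or _session_grid(truth, voxel)
    contrast = ImageVolume(_t1w_contrast(truth), truth.grid)
    world_map = None
    if session == "petmr":
        # session world -> phantom world
        world_map = truth.session_transform_true.inverse().matrix
    vol = resample(contrast, g, world_map=world_map, order=1, cval=_T1W_LEVELS[BACKGROUND])
    data = np.nan_to_num(vol.data, nan=_T1W_LEVELS[BACKGROUND])
    landmark_world = truth.grid.index_to_world(
        [0.0, 0.0, float(truth.bifurcation_slice)]
    )
    landmark_world[:2] = truth.grid.center_world[:2]
    if session == "petmr":
        landmark_world = truth.session_transform_true.apply(landmark_world)
    k = int(np.clip(np.rint(g.world_to_index(landmark_world)[2]), 0, g.shape[2] - 1))
    return T1WVolume(data=data, grid=g, meta={"session": session}, landmark_slice=k)


def render_pet(
    truth: PhantomTruth,
    psf_fwhm_mm: float = 3.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    in_session_frame: bool = True,
):
    """Render the PET activity volume on the 1.2 x 1.2 x 2.78 mm PET grid.

    The truth activity is convolved with an isotropic Gaussian point-spread
    function of the given FWHM (the scanner's ~3 mm effective resolution in
    neck reconstructions; 0 disables the blur for exact round-trip checks),
    optionally displaced into the PET/MR session frame, resampled, and
    Gaussian noise added.  Metadata carries the 3 MBq/kg dosing.
    """
    from .petquant import PETStudy

    if psf_fwhm_mm < 0:
        raise ValueError("psf_fwhm_mm must be non-negative")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    act = truth.activity_map.astype(float)
    if psf_fwhm_mm > 0:
        sigma_mm = psf_fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        sigma_vox = sigma_mm / np.asarray(truth.grid.voxel_size)
        act = ndimage.gaussian_filter(act, sigma_vox, mode="nearest")
    g = _session_grid(truth, PET_VOXEL)
    world_map = (
        truth.session_transform_true.inverse().matrix if in_session_frame else None
    )
    vol = resample(ImageVolume(act, truth.grid), g, world_map=world_map, order=1, cval=0.0)
    data = np.nan_to_num(vol.data)
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        data = np.maximum(data + rng.normal(0.0, noise_sd, data.shape), 0.0)
    return PETStudy(
        activity=data,
        grid=g,
        injected_dose_mbq=truth.injected_dose,
        body_weight_kg=truth.body_weight,
        meta={"psf_fwhm_mm": psf_fwhm_mm, "seed": seed, "session": in_session_frame},
    )


def blood_sample_points(
    truth: PhantomTruth, n: int = 6, in_session_frame: bool = True
) -> np.ndarray:
    """World coordinates of ``n`` lumen (venous blood stand-in) sample points.

    Points sit on the vessel axis at evenly spaced slices, away from the
    volume edges; for a session-frame PET volume they are mapped through
    the true session transform.
    """
    nz = truth.grid.shape[2]
    # keep clear of the stack ends so the points survive the session
    # displacement into the PET volume
    ks = np.linspace(0.2 * (nz - 1), 0.8 * (nz - 1), n)
    c = truth.grid.center_world
    pts = np.array([[c[0], c[1], truth.grid.index_to_world([0, 0, k])[2]] for k in ks])
    if in_session_frame:
        pts = truth.session_transform_true.apply(pts)
    return pts
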