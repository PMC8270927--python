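"""Digital phantom construction and forward rendering."""

import dataclasses

import numpy as np
import pytest

from plaquekit import dixon, phantom
from plaquekit.grid import GridGeometry, ImageVolume, resample
from plaquekit.phantom import PhantomConfig, make_phantom, render_dixon, render_pet, render_t1w


def test_phantom_is_deterministic():
    a = make_phantom(seed=5)
    b = make_phantom(seed=5)
    assert np.array_equal(a.water_map, b.water_map)
    assert np.array_equal(a.fat_map, b.fat_map)
    assert np.array_equal(a.r2star_map, b.r2star_map)
    assert np.array_equal(a.activity_map, b.activity_map)
    assert a.session_transform_true == b.session_transform_true


def test_configured_levels_are_attained(truth):
    """Plaque contains a lipid-core voxel at >= the configured FF and a
    hemorrhage voxel at >= the configured R2*."""
    cfg = truth.config
    m = truth.plaque_mask_true
    assert m.any()
    assert np.nanmax(truth.fat_fraction_map[m]) >= cfg.lipid_core_ff
    assert truth.r2star_map[m].max() >= cfg.hemorrhage_r2star


def test_plaque_mask_inside_wall_and_thick_enough(truth):
    # mask voxels never sit in the lumen, and the protrusion meets the
    # 1.5 mm plaque definition
    assert not (truth.plaque_mask_true & (truth.compartments == phantom.LUMEN)).any()
    assert truth.config.plaque_protrusion >= 1.5


def test_ff_in_unit_interval(truth):
    total = truth.water_map + truth.fat_map
    ff = truth.fat_fraction_map[total > 0]
    assert np.nanmin(ff) >= 0 and np.nanmax(ff) <= 1


def test_zero_extent_plaque_is_degenerate_and_empty():
    cfg = dataclasses.replace(PhantomConfig(), plaque_extent_deg=0.0)
    t = make_phantom(cfg, seed=0)
    assert t.degenerate
    assert t.plaque_mask_true.sum() == 0


def test_oversized_vessel_rejected():
    cfg = dataclasses.replace(PhantomConfig(), lumen_radius=15.0)
    with pytest.raises(ValueError, match="field of view"):
        make_phantom(cfg, seed=0)


def test_sub_plaque_protrusion_rejected():
    cfg = dataclasses.replace(PhantomConfig(), plaque_protrusion=1.0)
    with pytest.raises(ValueError, match="1.5 mm"):
        make_phantom(cfg, seed=0)


def test_dixon_render_noiseless_matches_forward_model(truth):
    series = render_dixon(truth, noise_sd=0.0, seed=0)
    te, vol = series.echoes[0]
    expected = dixon.forward_signal(
        truth.water_map, truth.fat_map, truth.r2star_map, te
    )
    assert np.allclose(vol, expected)


def test_dixon_in_phase_short_te_limit(truth):
    """At Te -> 0 on the in-phase cycle the signal approaches W + F."""
    s = dixon.forward_signal(truth.water_map, truth.fat_map, truth.r2star_map, 1e-6)
    assert np.allclose(s, truth.water_map + truth.fat_map, atol=1e-4)


def test_dixon_render_rejects_negative_noise(truth):
    with pytest.raises(ValueError):
        render_dixon(truth, noise_sd=-0.1)


def test_dixon_noise_is_rician_and_seeded(truth):
    a = render_dixon(truth, noise_sd=0.05, seed=9)
    b = render_dixon(truth, noise_sd=0.05, seed=9)
    assert np.array_equal(a.echoes[0][1], b.echoes[0][1])
    # magnitude data: strictly non-negative even where the model is ~0
    assert np.min(a.echoes[0][1]) >= 0


def test_t1w_sessions_and_grids(truth):
    sa = render_t1w(truth, "standalone")
    pm = render_t1w(truth, "petmr")
    assert sa.grid.voxel_size == phantom.T1W_STANDALONE_VOXEL
    assert pm.grid.voxel_size == phantom.T1W_PETMR_VOXEL
    with pytest.raises(ValueError, match="session"):
        render_t1w(truth, "clinic")


def test_t1w_requested_grid_is_respected(truth):
    g = GridGeometry((30, 30, 8), (0.8, 0.8, 3.0))
    vol = render_t1w(truth, "standalone", grid=g)
    assert vol.grid == g and vol.data.shape == g.shape


def test_t1w_translation_recovered_by_shift_search(truth):
    """A pure 2 mm x-translation moves the cross-correlation peak 2 mm."""
    from plaquekit.register import SimilarityTransform

    sa = render_t1w(truth, "standalone")
    t = SimilarityTransform(translation=(2.0, 0, 0))
    shifted = resample(ImageVolume(sa.data, sa.grid), sa.grid, world_map=t.matrix)
    a = np.nan_to_num(sa.data - np.nanmean(sa.data))
    b = np.nan_to_num(shifted.data - np.nanmean(shifted.data))
    # brute-force integer shift search along x (voxel 0.5 mm => 4 voxels)
    scores = [
        np.sum(a[8:-8] * np.roll(b, -k, axis=0)[8:-8]) for k in range(-8, 9)
    ]
    best = range(-8, 9)[int(np.argmax(scores))]
    assert abs(best) * sa.grid.voxel_size[0] == pytest.approx(2.0, abs=0.5)


def test_identity_session_renders_match_up_to_resampling():
    cfg = dataclasses.replace(
        PhantomConfig(),
        session_max_translation=0.0,
        session_max_rotation_deg=0.0,
        session_scale_range=(1.0, 1.0),
    )
    t = make_phantom(cfg, seed=2)
    sa = render_t1w(t, "standalone")
    pm = render_t1w(t, "petmr", grid=sa.grid)  # same target grid isolates the transform
    assert np.allclose(sa.data, pm.data, atol=1e-6)


def test_pet_uniform_activity_stays_uniform():
    cfg = PhantomConfig()
    t = make_phantom(cfg, seed=3)
    t.activity_map[:] = 2.0
    study = render_pet(t, psf_fwhm_mm=3.0, noise_sd=0.0, in_session_frame=False)
    inner = study.activity[2:-2, 2:-2, 1:-1]
    assert np.allclose(inner, 2.0, atol=1e-6)


def test_pet_conserves_activity_for_interior_source():
    t = make_phantom(seed=4)
    t.activity_map[:] = 0.0
    t.activity_map[18:22, 18:22, 16:20] = 5.0
    blurred = render_pet(t, psf_fwhm_mm=3.0, noise_sd=0.0, in_session_frame=False)
    # compare total activity (kBq) on the phantom grid vs the PET grid
    total_in = t.activity_map.sum() * t.grid.voxel_volume_mm3
    total_out = blurred.activity.sum() * blurred.grid.voxel_volume_mm3
    assert total_out == pytest.approx(total_in, rel=5e-3)


def _profile_fwhm(profile, dx):
    """FWHM of a peaked 1-D profile via linear interpolation of crossings."""
    peak = int(np.argmax(profile))
    half = profile[peak] / 2.0
    left = np.interp(half, profile[: peak + 1], np.arange(peak + 1) * dx)
    right_seg = profile[peak:][::-1]
    right = np.interp(half, right_seg, np.arange(len(right_seg))[::-1] * dx + peak * dx)
    return right - left


def test_pet_point_source_fwhm_matches_psf():
    """The rendered PET profile of a point source has ~ the requested FWHM."""
    t = make_phantom(seed=4)
    t.activity_map[:] = 0.0
    t.activity_map[20, 20, 18] = 100.0
    study = render_pet(t, psf_fwhm_mm=3.0, noise_sd=0.0, in_session_frame=False)
    i, j, k = np.unravel_index(np.argmax(study.activity), study.activity.shape)
    profile = study.activity[:, j, k]
    fwhm = _profile_fwhm(profile, study.grid.voxel_size[0])
    assert fwhm == pytest.approx(3.0, abs=study.grid.voxel_size[0])


def test_pet_metadata_carries_weight_based_dose(truth):
    study = render_pet(truth, noise_sd=0.0)
    assert study.injected_dose_mbq == pytest.approx(3.0 * truth.body_weight)
    assert study.body_weight_kg == truth.body_weight


def test_pet_deterministic_and_rejects_bad_psf(truth):
    a = render_pet(truth, psf_fwhm_mm=3.0, noise_sd=0.0, seed=0)
    b = render_pet(truth, psf_fwhm_mm=3.0, noise_sd=0.0, seed=0)
    assert np.array_equal(a.activity, b.activity)
    with pytest.raises(ValueError):
        render_pet(truth, psf_fwhm_mm=-1.0)
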