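"""Similarity transforms, mutual information and registration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plaquekit import phantom
from plaquekit.grid import GridGeometry, ImageVolume, resample
from plaquekit.register import (
    RegistrationConfig,
    SimilarityTransform,
    align_slices,
    apply_to_mask,
    joint_histogram,
    mattes_mi,
    register_similarity,
)
FAST = RegistrationConfig(max_iter=600)


@given(
    tx=st.floats(-5, 5),
    ty=st.floats(-5, 5),
    tz=st.floats(-5, 5),
    rx=st.floats(-20, 20),
    ry=st.floats(-20, 20),
    rz=st.floats(-20, 20),
    s=st.floats(0.8, 1.25),
)
@settings(max_examples=50, deadline=None, derandomize=True)
def test_transform_composed_with_inverse_is_identity(tx, ty, tz, rx, ry, rz, s):
    t = SimilarityTransform((tx, ty, tz), (rx, ry, rz), s, center=(3.0, -2.0, 1.0))
    m = t.matrix @ t.inverse().matrix
    assert np.allclose(m, np.eye(4), atol=1e-8)


def test_transform_rejects_reflection_and_zero_scale():
    with pytest.raises(ValueError):
        SimilarityTransform(scale=0.0)
    with pytest.raises(ValueError):
        SimilarityTransform(scale=-1.0)


def test_transform_apply_matches_matrix():
    t = SimilarityTransform((1, 2, 3), (0, 0, 90), 2.0, center=(0, 0, 0))
    # 90 deg about z, doubled: (1,0,0) -> (0,2,0), plus translation
    assert np.allclose(t.apply([1, 0, 0]), [1, 4, 3], atol=1e-12)


def test_mi_self_is_maximal_and_shift_lowers_it(t1w):
    ident = SimilarityTransform.identity(tuple(t1w.grid.center_world))
    mi_self = mattes_mi(t1w, t1w, ident)
    shift = SimilarityTransform(translation=(2.5, 0, 0))
    assert mi_self > mattes_mi(t1w, t1w, shift)


def test_mi_against_constant_is_zero(t1w):
    flat = ImageVolume(np.full(t1w.grid.shape, 1.0), t1w.grid)
    assert mattes_mi(t1w, flat) == pytest.approx(0.0, abs=1e-12)


def test_mi_agrees_with_sklearn_on_joint_histogram(t1w):
    """Independent cross-check of the MI value for a fixed joint histogram."""
    sklearn_metrics = pytest.importorskip("sklearn.metrics")
    from plaquekit.register import mutual_information

    hist = joint_histogram(t1w, t1w, SimilarityTransform.identity(), bins=32)
    ours = mutual_information(hist)
    # sklearn computes MI of a contingency table in nats
    theirs = sklearn_metrics.mutual_info_score(None, None, contingency=hist)
    assert ours == pytest.approx(theirs, rel=1e-10)


def test_mi_invariant_to_monotone_rescale(truth):
    """A monotone (quadratic) intensity rescale leaves MI unchanged as long
    as distinct tissue levels stay in distinct bins."""
    levels = np.array([0.35, 0.10, 0.65, 0.85])  # per-compartment contrast
    img = ImageVolume(levels[truth.compartments], truth.grid)
    ident = SimilarityTransform.identity()
    mi0 = mattes_mi(img, img, ident)
    sq = ImageVolume(np.asarray(img.data) ** 2, img.grid)
    mi1 = mattes_mi(img, sq, ident)
    assert mi1 == pytest.approx(mi0, rel=1e-10)


def test_mi_bins_validated(t1w):
    with pytest.raises(ValueError):
        mattes_mi(t1w, t1w, bins=4)


def test_register_self_returns_near_identity(t1w):
    res = register_similarity(t1w, t1w, seed=1, config=FAST)
    assert not res.degenerate
    assert np.allclose(res.transform.translation, 0, atol=0.1)
    assert np.allclose(res.transform.rotation_deg, 0, atol=0.1)
    assert res.transform.scale == pytest.approx(1.0, abs=0.001)


def test_register_degenerate_image_flags(t1w):
    flat = ImageVolume(np.zeros(t1w.grid.shape), t1w.grid)
    res = register_similarity(t1w, flat, seed=1, config=FAST)
    assert res.degenerate
    assert res.transform.scale == 1.0


def test_register_recovers_known_translation(t1w):
    pert = SimilarityTransform(
        translation=(2.0, -1.0, 0.0), center=tuple(t1w.grid.center_world)
    )
    moving = resample(ImageVolume(t1w.data, t1w.grid), t1w.grid, world_map=pert.matrix)
    moving = ImageVolume(np.nan_to_num(moving.data, nan=0.35), t1w.grid)
    res = register_similarity(t1w, moving, seed=2)
    err = np.array(res.transform.translation) - np.array(pert.inverse().translation)
    assert np.all(np.abs(err) <= 0.5 * np.array(t1w.grid.voxel_size))


def test_register_recovers_known_scaling(t1w):
    pert = SimilarityTransform(scale=1.05, center=tuple(t1w.grid.center_world))
    moving = resample(ImageVolume(t1w.data, t1w.grid), t1w.grid, world_map=pert.matrix)
    moving = ImageVolume(np.nan_to_num(moving.data, nan=0.35), t1w.grid)
    res = register_similarity(t1w, moving, seed=2)
    assert res.transform.scale == pytest.approx(1.0 / 1.05, abs=0.01)


def test_apply_to_mask_identity_roundtrip(truth):
    mask = truth.plaque_mask()
    out = apply_to_mask(mask, SimilarityTransform.identity(), truth.grid)
    assert np.array_equal(out.voxels, mask.voxels)


def test_apply_to_mask_slice_shift(truth):
    mask = truth.plaque_mask()
    dz = truth.grid.voxel_size[2]
    shift = SimilarityTransform(translation=(0, 0, dz))
    out = apply_to_mask(mask, shift, truth.grid)
    # out(z) = mask(z + dz): slice ids move down by one
    assert np.array_equal(np.asarray(out.slice_ids), np.asarray(mask.slice_ids) - 1)


def test_apply_to_mask_session_transfer_dice(truth):
    """Truth mask carried to the session frame and back overlaps >= 0.8."""
    sess = truth.session_transform_true
    pm_grid = phantom.render_t1w(truth, "petmr").grid
    in_session = apply_to_mask(truth.plaque_mask(), sess.inverse(), pm_grid)
    back = apply_to_mask(in_session, sess, truth.grid)
    inter = (back.voxels & truth.plaque_mask_true).sum()
    dice = 2 * inter / (back.voxels.sum() + truth.plaque_mask_true.sum())
    assert dice >= 0.8


def test_apply_to_mask_preserves_volume(truth):
    """Voxel count maps with the voxel-volume ratio (within 20%)."""
    sess = truth.session_transform_true
    pm_grid = phantom.render_t1w(truth, "petmr").grid
    out = apply_to_mask(truth.plaque_mask(), sess.inverse(), pm_grid)
    ratio = truth.grid.voxel_volume_mm3 / pm_grid.voxel_volume_mm3
    expected = truth.plaque_mask_true.sum() * ratio
    assert out.n_voxels == pytest.approx(expected, rel=0.2)


def test_apply_to_mask_empty_result_is_flagged(truth):
    far = SimilarityTransform(translation=(500.0, 0, 0))
    out = apply_to_mask(truth.plaque_mask(), far, truth.grid)
    assert out.meta["empty"] and out.n_voxels == 0


def _grid(nz, dz):
    return GridGeometry((4, 4, nz), (1.0, 1.0, dz))


def test_align_slices_identity():
    c = align_slices(_grid(10, 2.0), _grid(10, 2.0), 3, 3)
    assert c.mapping == {i: i for i in range(10)}
    assert c.mapping[c.landmark_source] == c.landmark_target


def test_align_slices_mixed_thickness_arithmetic():
    # 1.75 mm source vs 2.5 mm target, landmarks at 0: the source slice at
    # +3.50 mm maps to the target slice at +2.5 mm (nearest of 2.5 vs 5.0)
    c = align_slices(_grid(8, 1.75), _grid(8, 2.5), 0, 0)
    assert c.mapping[2] == 1
    # and ties (e.g. +1.25 mm from 2.5/2) break toward the landmark
    c2 = align_slices(_grid(8, 1.25), _grid(8, 2.5), 0, 0)
    assert c2.mapping[1] == 0


def test_align_slices_landmark_offset_shifts_mapping():
    base = align_slices(_grid(10, 2.0), _grid(10, 2.0), 3, 3)
    off = align_slices(_grid(10, 2.0), _grid(10, 2.0), 3, 5)
    shifted = {i: j + 2 for i, j in base.mapping.items() if j + 2 <= 9}
    assert {i: off.mapping[i] for i in shifted if i in off.mapping} == shifted


def test_align_slices_monotone(truth):
    c = align_slices(_grid(20, 0.7), _grid(9, 2.78), 5, 4)
    vals = [c.mapping[k] for k in sorted(c.mapping)]
    assert all(b >= a for a, b in zip(vals, vals[1:]))


def test_align_slices_drops_slices_beyond_target_extent():
    c = align_slices(_grid(10, 2.0), _grid(2, 1.0), 0, 0)
    # target covers only 0..1 mm past the landmark: distant source slices drop
    assert c.mapping == {0: 0}
    assert not c.empty


def test_align_slices_validates_landmarks():
    with pytest.raises(ValueError):
        align_slices(_grid(4, 1.0), _grid(4, 1.0), 7, 0)
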