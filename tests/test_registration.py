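"""Rigid registration, axis alignment, masks and the common region."""

import numpy as np
import pytest

import remodel as rm


def _recovery_error(result, true_transform, voxel_size):
    comp = result.transform.compose(true_transform)
    rot = np.rad2deg(np.abs(comp.parameters()[:3])).max()
    trans = np.abs(comp.parameters()[3:]).max() / voxel_size
    return rot, trans


def test_self_registration_is_identity(clean_phantom):
    _, img, _ = clean_phantom
    res = rm.register_rigid(img, img)
    assert np.abs(res.transform.parameters()[:3]).max() < 1e-4       # rad
    assert np.abs(res.transform.parameters()[3:]).max() < 1e-3 * img.voxel_size
    assert res.converged


def _misaligned_scan(params, img, masks, T, noise_sd=0.0, seed=5):
    """Repeat-scan emulation: reposition the continuing geometry, re-window."""
    moved, _ = rm.simulate_followup(img, masks, np.zeros(img.shape),
                                    rm.MechanoregRule(event_rate=0.0),
                                    misalignment=T, seed=seed,
                                    noise_sd=noise_sd, params=params)
    return moved


def test_known_transform_recovered_noise_free(clean_phantom):
    p, img, masks = clean_phantom
    T = rm.RigidTransform3D(np.deg2rad([5.0, -2.0, 3.0]),
                            (8 * p.voxel_size, -4 * p.voxel_size,
                             3 * p.voxel_size),
                            center=tuple(img.center_physical()))
    moved = _misaligned_scan(p, img, masks, T)
    res = rm.register_rigid(img, moved)
    rot, trans = _recovery_error(res, T, p.voxel_size)
    assert rot < 0.2 and trans < 0.2
    assert res.final_mse <= rm.registration._mse(
        img.values.astype(float), moved,
        rm.RigidTransform3D.identity(center=tuple(img.center_physical())))


def test_known_transform_recovered_under_noise(noisy_phantom):
    p, img, masks = noisy_phantom
    T = rm.RigidTransform3D(np.deg2rad([4.0, 3.0, -2.0]),
                            (6 * p.voxel_size, 5 * p.voxel_size,
                             -4 * p.voxel_size),
                            center=tuple(img.center_physical()))
    moved = _misaligned_scan(p, img, masks, T, noise_sd=60.0)
    res = rm.register_rigid(img, moved)
    rot, trans = _recovery_error(res, T, p.voxel_size)
    assert rot < 0.5 and trans < 0.5


def test_constant_image_rejected():
    img = rm.DensityImage(np.full((8, 8, 8), 100.0))
    with pytest.raises(ValueError, match="gradient"):
        rm.register_rigid(img, img)


# ---------------------------------------------------------------------------
# axis alignment


def _cylinder(tilt_deg: float = 0.0, shape=(40, 32, 32), radius=8.0):
    z, y, x = np.mgrid[:shape[0], :shape[1], :shape[2]].astype(float)
    c = [(s - 1) / 2.0 for s in shape]
    t = np.deg2rad(tilt_deg)
    axis = np.array([np.sin(t), 0.0, np.cos(t)])  # (x, y, z), tilt about y
    p = np.stack([x - c[2], y - c[1], z - c[0]], axis=-1)
    along = p @ axis
    perp = p - along[..., None] * axis
    # cap the ends perpendicular to the cylinder's own axis so the shape is
    # a true finite cylinder (z-plane cuts would shear the inertia axis)
    inside = (np.linalg.norm(perp, axis=-1) <= radius) & (np.abs(along) <= 15)
    vals = np.where(inside, 900.0, 0.0)
    return rm.DensityImage(vals.astype(np.float32), voxel_size=1.0)


def test_aligned_cylinder_needs_no_rotation():
    _, T = rm.align_to_axis(_cylinder(0.0))
    angle = np.rad2deg(np.arccos(np.clip((np.trace(T.matrix()) - 1) / 2, -1, 1)))
    assert angle < 0.5


def test_tilted_cylinder_tilt_recovered():
    _, T = rm.align_to_axis(_cylinder(7.0))
    angle = np.rad2deg(np.arccos(np.clip((np.trace(T.matrix()) - 1) / 2, -1, 1)))
    assert abs(angle - 7.0) < 0.5


def test_axis_invariant_to_density_rescaling():
    img = _cylinder(5.0)
    _, T1 = rm.align_to_axis(img)
    _, T2 = rm.align_to_axis(rm.DensityImage(img.values * 2.5, img.voxel_size))
    assert np.abs(T1.parameters() - T2.parameters()).max() < 1e-6


def test_isotropic_cloud_has_no_axis():
    img = rm.DensityImage(np.full((20, 20, 20), 900.0, np.float32))
    with pytest.raises(ValueError, match="axis"):
        rm.align_to_axis(img)


# ---------------------------------------------------------------------------
# mask generation


def _dice(a, b):
    return 2 * (a & b).sum() / (a.sum() + b.sum())


def test_generated_masks_match_phantom_geometry(noisy_phantom):
    _, img, truth = noisy_phantom
    masks = rm.generate_masks(img)
    assert _dice(masks.cortical, truth.cortical) >= 0.95
    assert _dice(masks.whole, truth.whole) >= 0.95
    # BoneMasks invariants are enforced on construction; re-check disjointness
    assert not np.any(masks.cortical & masks.trabecular)
    assert np.all(masks.cortical <= masks.whole)
    assert np.all(masks.trabecular <= masks.whole)


def test_all_air_image_raises():
    with pytest.raises(ValueError, match="empty"):
        rm.generate_masks(rm.DensityImage(np.zeros((10, 10, 10), np.float32)))


# ---------------------------------------------------------------------------
# common region


def _prism_masks(shape=(20, 12, 12)):
    whole = np.zeros(shape, bool)
    whole[:, 2:10, 2:10] = True
    empty = np.zeros(shape, bool)
    return rm.BoneMasks(whole=whole, cortical=empty, trabecular=empty.copy())


def test_common_region_identity_is_whole_mask():
    masks = _prism_masks()
    img = rm.DensityImage(np.zeros(masks.whole.shape, np.float32), voxel_size=1.0)
    region = rm.common_region(masks, masks, rm.RigidTransform3D.identity(), img)
    np.testing.assert_array_equal(region, masks.whole)


def test_z_shift_removes_exactly_that_many_slices():
    masks = _prism_masks()
    img = rm.DensityImage(np.zeros(masks.whole.shape, np.float32), voxel_size=1.0)
    T = rm.RigidTransform3D(translation=(0.0, 0.0, 10.0))
    region = rm.common_region(masks, masks, T, img)
    assert int((region.any(axis=(1, 2))).sum()) == masks.whole.shape[0] - 10


def test_overlap_volume_symmetric_under_argument_swap():
    masks = _prism_masks()
    img = rm.DensityImage(np.zeros(masks.whole.shape, np.float32), voxel_size=1.0)
    T = rm.RigidTransform3D(translation=(2.0, 1.0, 6.0))
    v1 = rm.common_region(masks, masks, T, img).sum()
    v2 = rm.common_region(masks, masks, T.inverse(), img).sum()
    assert v1 == v2


def test_empty_overlap_raises():
    masks = _prism_masks()
    img = rm.DensityImage(np.zeros(masks.whole.shape, np.float32), voxel_size=1.0)
    T = rm.RigidTransform3D(translation=(0.0, 0.0, 100.0))
    with pytest.raises(ValueError, match="empty"):
        rm.common_region(masks, masks, T, img)
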