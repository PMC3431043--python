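"""Rigid / affine / thin-plate-spline fitting and application."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mothatlas as ma
from mothatlas.transforms import DegenerateFitError

from conftest import random_tree, ball_stack


def lm(points, prefix="p"):
    return ma.LandmarkSet.from_mapping(
        {f"{prefix}{k}": p for k, p in enumerate(np.atleast_2d(points))})


def rot_z(deg):
    a = np.deg2rad(deg)
    return np.array([[np.cos(a), -np.sin(a), 0],
                     [np.sin(a), np.cos(a), 0],
                     [0, 0, 1.0]])


# ---------------------------------------------------------------------------
# Rigid
# ---------------------------------------------------------------------------

def test_rigid_identity_on_equal_sets(rng):
    pts = rng.uniform(0, 100, (6, 3))
    T = ma.fit_rigid(lm(pts), lm(pts))
    np.testing.assert_allclose(T.rotation, np.eye(3), atol=1e-12)
    np.testing.assert_allclose(T.translation, 0, atol=1e-10)


def test_rigid_recovers_known_rotation_translation(rng):
    src = rng.uniform(0, 100, (10, 3))
    R, t = rot_z(30.0), np.array([5.0, -3.0, 2.0])
    dst = src @ R.T + t
    T = ma.fit_rigid(lm(src), lm(dst))
    rms = np.sqrt(np.mean((T.apply(src) - dst) ** 2))
    assert rms < 1e-9
    np.testing.assert_allclose(T.rotation, R, atol=1e-9)
    assert np.linalg.det(T.rotation) == pytest.approx(1.0, abs=1e-12)


def test_pure_translation_gives_identity_rotation(rng):
    src = rng.uniform(0, 100, (5, 3))
    T = ma.fit_rigid(lm(src), lm(src + np.array([7.0, 1.0, -4.0])))
    np.testing.assert_allclose(T.rotation, np.eye(3), atol=1e-12)
    np.testing.assert_allclose(T.translation, [7, 1, -4], atol=1e-10)


def test_rigid_never_returns_reflection(rng):
    """A mirrored destination cannot trick the fit into det = -1."""
    src = rng.uniform(0, 100, (8, 3))
    dst = src.copy()
    dst[:, 0] *= -1.0
    T = ma.fit_rigid(lm(src), lm(dst))
    assert np.linalg.det(T.rotation) == pytest.approx(1.0, abs=1e-9)


def test_rigid_degenerate_inputs():
    line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3.0, 0, 0]])
    with pytest.raises(DegenerateFitError, match="collinear"):
        ma.fit_rigid(lm(line), lm(line + 1.0))
    two = np.array([[0, 0, 0], [1.0, 1, 1]])
    with pytest.raises(DegenerateFitError, match=">= 3"):
        ma.fit_rigid(lm(two), lm(two))


def test_rigid_composition_and_inverse(rng):
    src = rng.uniform(0, 50, (6, 3))
    T = ma.fit_rigid(lm(src), lm(src @ rot_z(40).T + [1, 2, 3]))
    pts = rng.uniform(0, 50, (20, 3))
    np.testing.assert_allclose(T.inverse().apply(T.apply(pts)), pts, atol=1e-9)
    I = T.compose(T.inverse())
    np.testing.assert_allclose(I.apply(pts), pts, atol=1e-9)


# ---------------------------------------------------------------------------
# Affine
# ---------------------------------------------------------------------------

def test_affine_recovers_uniform_scale(rng):
    src = rng.uniform(0, 10, (8, 3))
    T = ma.fit_affine(lm(src), lm(2.0 * src))
    np.testing.assert_allclose(T.matrix, 2 * np.eye(3), atol=1e-9)
    np.testing.assert_allclose(T.translation, 0, atol=1e-8)


def test_affine_recovers_shear_on_cube_corners():
    corners = np.array([[x, y, z] for x in (0, 10) for y in (0, 10)
                        for z in (0, 10)], dtype=float)
    A = np.array([[1.0, 0.3, 0.0], [0.0, 1.0, -0.2], [0.1, 0.0, 1.0]])
    t = np.array([4.0, -1.0, 2.0])
    T = ma.fit_affine(lm(corners), lm(corners @ A.T + t))
    np.testing.assert_allclose(T.matrix, A, atol=1e-9)
    np.testing.assert_allclose(T.translation, t, atol=1e-8)


def test_affine_needs_four_noncoplanar_pairs(rng):
    three = rng.uniform(0, 10, (3, 3))
    with pytest.raises(DegenerateFitError, match=">= 4"):
        ma.fit_affine(lm(three), lm(three))
    plane = rng.uniform(0, 10, (6, 3))
    plane[:, 2] = 5.0
    with pytest.raises(DegenerateFitError, match="coplanar"):
        ma.fit_affine(lm(plane), lm(plane))


# ---------------------------------------------------------------------------
# Thin-plate spline
# ---------------------------------------------------------------------------

def test_tps_identity_when_dst_equals_src(rng):
    src = rng.uniform(0, 100, (10, 3))
    T = ma.fit_tps(lm(src), lm(src))
    assert T.warp_norm() < 1e-8
    pts = rng.uniform(0, 100, (50, 3))
    np.testing.assert_allclose(T.apply(pts), pts, atol=1e-6)


def test_tps_matches_affine_for_affine_consistent_landmarks(rng):
    src = rng.uniform(0, 100, (12, 3))
    A = np.array([[1.1, 0.2, 0.0], [-0.1, 0.9, 0.1], [0.0, 0.1, 1.2]])
    t = np.array([5.0, -2.0, 1.0])
    dst = src @ A.T + t
    tps = ma.fit_tps(lm(src), lm(dst))
    aff = ma.fit_affine(lm(src), lm(dst))
    assert tps.warp_norm() < 1e-8
    pts = rng.uniform(-20, 120, (100, 3))
    np.testing.assert_allclose(tps.apply(pts), aff.apply(pts), atol=1e-6)


def test_tps_interpolates_perturbed_landmarks(rng):
    src = rng.uniform(0, 200, (12, 3))
    dst = src + rng.uniform(-20, 20, (12, 3))
    T = ma.fit_tps(lm(src), lm(dst))
    err = np.linalg.norm(T.apply(src) - dst, axis=1)
    assert err.max() < 1e-6


def test_tps_side_conditions(rng):
    src = rng.uniform(0, 100, (9, 3))
    dst = src + rng.uniform(-15, 15, (9, 3))
    T = ma.fit_tps(lm(src), lm(dst))
    np.testing.assert_allclose(T.warp.sum(axis=0), 0, atol=1e-8)
    np.testing.assert_allclose(T.source.T @ T.warp, 0, atol=1e-6)


def test_tps_minimum_landmark_count(rng):
    three = rng.uniform(0, 10, (3, 3))
    with pytest.raises(DegenerateFitError, match=">= 4"):
        ma.fit_tps(lm(three), lm(three))


def test_tps_regularization_smooths(rng):
    src = rng.uniform(0, 100, (10, 3))
    dst = src + rng.uniform(-10, 10, (10, 3))
    exact = ma.fit_tps(lm(src), lm(dst), lam=0.0)
    smooth = ma.fit_tps(lm(src), lm(dst), lam=100.0)
    res_exact = np.linalg.norm(exact.apply(src) - dst, axis=1).max()
    res_smooth = np.linalg.norm(smooth.apply(src) - dst, axis=1).max()
    assert res_exact < 1e-6 < res_smooth
    assert smooth.warp_norm() < exact.warp_norm()


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(min_value=4, max_value=30), st.integers(0, 2 ** 31 - 1))
def test_tps_interpolation_property(n, seed):
    """TPS with lam=0 hits every landmark for any non-degenerate set."""
    r = np.random.default_rng(seed)
    src = r.uniform(0, 100, (n, 3))
    sv = np.linalg.svd(src - src.mean(axis=0), compute_uv=False)
    if sv[2] < 1e-3 * sv[0]:  # nearly coplanar draw: skip silently
        return
    dst = src + r.uniform(-20, 20, (n, 3))
    T = ma.fit_tps(lm(src), lm(dst))
    assert np.linalg.norm(T.apply(src) - dst, axis=1).max() < 1e-6


# ---------------------------------------------------------------------------
# Application to points / morphologies / stacks
# ---------------------------------------------------------------------------

def test_apply_points_rigid_preserves_distances(rng):
    src = rng.uniform(0, 100, (5, 3))
    T = ma.fit_rigid(lm(src), lm(src @ rot_z(25).T + [3, 1, -2]))
    pts = rng.uniform(0, 100, (2, 3))
    out = ma.apply_points(T, pts)
    assert np.linalg.norm(out[0] - out[1]) == pytest.approx(
        np.linalg.norm(pts[0] - pts[1]), abs=1e-9)


def test_apply_morphology_identity_and_topology(rng):
    m = random_tree(5)
    out = ma.apply_morphology(ma.IdentityTransform(), m)
    np.testing.assert_array_equal(out.parent_ids, m.parent_ids)
    np.testing.assert_allclose(out.xyz, m.xyz)
    np.testing.assert_allclose(out.radii, m.radii)


def test_apply_morphology_local_scale_doubles_radii(rng):
    m = random_tree(6)
    T = ma.AffineTransform(2.0 * np.eye(3), np.zeros(3))
    out = ma.apply_morphology(T, m, radius_policy="local_scale")
    np.testing.assert_allclose(out.radii, 2.0 * m.radii, rtol=1e-9)
    assert out.total_length() == pytest.approx(2.0 * m.total_length())


def test_apply_morphology_rigid_fixed_conserves_cable(rng):
    m = random_tree(7)
    src = rng.uniform(0, 100, (5, 3))
    T = ma.fit_rigid(lm(src), lm(src @ rot_z(70).T + [10, 0, 5]))
    out = ma.apply_morphology(T, m)
    np.testing.assert_array_equal(out.radii, m.radii)
    assert out.total_length() == pytest.approx(m.total_length(), rel=1e-12)
    np.testing.assert_array_equal(out.parent_ids, m.parent_ids)


def test_resample_identity_is_voxel_identity(rng):
    vol = rng.integers(0, 255, (8, 10, 12), dtype=np.uint8)
    s = ma.ImageStack(vol, spacing=(2, 1, 1))
    out = ma.resample_image(ma.IdentityTransform(), s)
    np.testing.assert_array_equal(out.voxels, vol)


def test_resample_integer_voxel_shift(rng):
    vol = rng.integers(0, 255, (8, 10, 12), dtype=np.uint8)
    s = ma.ImageStack(vol, spacing=(2.0, 1.0, 1.0))
    T = ma.RigidTransform(np.eye(3), np.array([1.0, 0.0, 0.0]))  # +1 voxel in x
    out = ma.resample_image(T, s)
    np.testing.assert_array_equal(out.voxels[:, :, 1:], vol[:, :, :-1])
    assert np.all(out.voxels[:, :, 0] == 0)


def test_resample_affine_moves_ball_centroid():
    s = ball_stack(shape=(24, 40, 40), r=6.0, fg=200, bg=0)
    T = ma.AffineTransform(np.eye(3), np.array([5.0, -3.0, 2.0]))
    out = ma.resample_image(T, s)
    kji = np.argwhere(out.voxels > 100)
    centroid = out.index_to_physical(kji).mean(axis=0)
    orig = s.index_to_physical(np.argwhere(s.voxels > 100)).mean(axis=0)
    np.testing.assert_allclose(centroid, orig + [5, -3, 2], atol=0.5)


# ---------------------------------------------------------------------------
# Mirroring
# ---------------------------------------------------------------------------

def test_mirror_stack_is_involution(rng):
    s = ma.ImageStack(rng.integers(0, 255, (4, 6, 8), dtype=np.uint8))
    np.testing.assert_array_equal(
        ma.mirror(ma.mirror(s, "x"), "x").voxels, s.voxels)


def test_mirror_landmark_reflection_arithmetic():
    lms = ma.LandmarkSet.from_mapping({"RMC": (100.0, 50.0, 20.0)})
    out = ma.mirror(lms, axis="x", extent=300.0)
    np.testing.assert_allclose(out["RMC"], [200.0, 50.0, 20.0])


def test_mirror_morphology_preserves_cable_length():
    m = random_tree(9)
    out = ma.mirror(m, axis="y", extent=(0.0, 200.0))
    assert out.total_length() == pytest.approx(m.total_length(), rel=1e-12)


def test_swap_lr_names():
    lms = ma.LandmarkSet.from_mapping(
        {"CCB": (0, 0, 0), "RMC": (1, 0, 0), "LMC": (-1, 0, 0)})
    out = ma.swap_lr_names(lms)
    np.testing.assert_allclose(out["RMC"], [-1, 0, 0])
    np.testing.assert_allclose(out["LMC"], [1, 0, 0])
    np.testing.assert_allclose(out["CCB"], [0, 0, 0])
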