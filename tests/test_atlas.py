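"""Standard-brain construction: origin, alignment, averaging, outline, surface."""

import numpy as np
import pytest

import mothatlas as ma
from mothatlas.atlas import AtlasConfig, AtlasError

from conftest import ball_stack


def dice(a: np.ndarray, b: np.ndarray) -> float:
    a, b = a.astype(bool), b.astype(bool)
    return 2.0 * np.logical_and(a, b).sum() / (a.sum() + b.sum())


def brain_blob(shape=(48, 64, 64), spacing=(2.0, 1.0, 1.0)):
    """Two overlapping ellipsoids — a crude bilaterally symmetric brain."""
    grids = np.meshgrid(*[np.arange(n) * s for n, s in zip(shape, spacing)],
                        indexing="ij")
    z, y, x = grids
    cz, cy, cx = (shape[0] * spacing[0] / 2, shape[1] * spacing[1] / 2,
                  shape[2] * spacing[2] / 2)
    left = (((x - cx + 12) / 16) ** 2 + ((y - cy) / 14) ** 2
            + ((z - cz) / 18) ** 2) <= 1
    right = (((x - cx - 12) / 16) ** 2 + ((y - cy) / 14) ** 2
             + ((z - cz) / 18) ** 2) <= 1
    vol = np.where(left | right, 200, 15).astype(np.uint8)
    return ma.ImageStack(vol, spacing)


def blob_landmarks(stack):
    """Five named landmarks in the blob's frame (CCB + bilateral pairs)."""
    ext = stack.physical_extent()
    c = ext.mean(axis=1)
    return ma.LandmarkSet.from_mapping({
        "CCB": c,
        "RMC": c + [14, -6, 4],
        "LMC": c + [-14, -6, 4],
        "RAL": c + [10, 10, -6],
        "LAL": c + [-10, 10, -6],
    })


# ---------------------------------------------------------------------------
# set_brain_origin
# ---------------------------------------------------------------------------

def test_set_brain_origin_places_point_at_zero():
    s = ma.ImageStack(np.zeros((30, 40, 40), dtype=np.uint8), spacing=(2, 1, 1))
    out = ma.set_brain_origin(s, esophagus_center=(20.0, 25.0),
                              middle_slice_index=15)
    # the voxel at (k=15, y=25, x=20) is now the physical origin
    np.testing.assert_allclose(
        out.index_to_physical(np.array([15, 25, 20]))[0], [0, 0, 0], atol=1e-12)


def test_set_brain_origin_idempotent():
    s = ma.ImageStack(np.zeros((10, 16, 16), dtype=np.uint8), spacing=(2, 1, 1))
    once = ma.set_brain_origin(s, (8.0, 8.0), 5)
    twice = ma.set_brain_origin(once, (0.0, 0.0), 5)
    assert once.origin == twice.origin


def test_set_brain_origin_rejects_out_of_field():
    s = ma.ImageStack(np.zeros((10, 16, 16), dtype=np.uint8))
    with pytest.raises(ValueError, match="outside"):
        ma.set_brain_origin(s, (500.0, 8.0), 5)
    with pytest.raises(ValueError, match="slice"):
        ma.set_brain_origin(s, (8.0, 8.0), 99)


# ---------------------------------------------------------------------------
# averaging
# ---------------------------------------------------------------------------

def test_average_of_copies_is_the_stack(rng):
    s = ma.ImageStack(rng.integers(0, 255, (5, 6, 7), dtype=np.uint8))
    avg = ma.average_stacks([s, s.copy(), s.copy()])
    np.testing.assert_allclose(avg.voxels, s.voxels)


def test_average_of_constants():
    a = ma.ImageStack(np.zeros((4, 4, 4)))
    b = ma.ImageStack(np.full((4, 4, 4), 100.0))
    np.testing.assert_allclose(ma.average_stacks([a, b]).voxels, 50.0)


def test_average_permutation_invariant(rng):
    stacks = [ma.ImageStack(rng.integers(0, 255, (4, 5, 6), dtype=np.uint8))
              for _ in range(4)]
    fwd = ma.average_stacks(stacks)
    rev = ma.average_stacks(stacks[::-1])
    np.testing.assert_array_equal(fwd.voxels, rev.voxels)


def test_average_geometry_mismatch_rejected():
    a = ma.ImageStack(np.zeros((4, 4, 4)), spacing=(1, 1, 1))
    b = ma.ImageStack(np.zeros((4, 4, 4)), spacing=(2, 1, 1))
    with pytest.raises(ValueError, match="geometry"):
        ma.average_stacks([a, b])


# ---------------------------------------------------------------------------
# binarize + surface
# ---------------------------------------------------------------------------

def test_binarize_extracts_bright_ball():
    s = ball_stack(r=10.0, fg=200, bg=10)
    mask = ma.binarize_outline(s)
    truth = s.voxels > 100
    assert dice(mask.voxels, truth) > 0.99


def test_binarize_removes_distant_speck():
    s = ball_stack(r=10.0, fg=200, bg=10)
    vox = s.voxels.copy()
    vox[2, 2, 2] = 255  # lone bright speck far from the ball
    mask = ma.binarize_outline(ma.ImageStack(vox, s.spacing))
    assert mask.voxels[2, 2, 2] == 0
    assert mask.voxels.sum() > 0


def test_binarize_fills_hollow_shell():
    s = ball_stack(r=12.0, fg=200, bg=10)
    grids = np.meshgrid(*[np.arange(n) * sp for n, sp in
                          zip(s.shape, s.spacing)], indexing="ij")
    c = [n * sp / 2 for n, sp in zip(s.shape, s.spacing)]
    d2 = sum((g - cc) ** 2 for g, cc in zip(grids, c))
    vox = s.voxels.copy()
    vox[d2 <= 6.0 ** 2] = 10  # hollow out the centre
    mask = ma.binarize_outline(ma.ImageStack(vox, s.spacing))
    assert mask.voxels[tuple(int(cc) for cc in np.array(s.shape) // 2)] == 1


def test_binarize_empty_result_is_error():
    s = ma.ImageStack(np.full((4, 4, 4), 7, dtype=np.uint8))
    with pytest.raises(AtlasError):
        ma.binarize_outline(s)


def test_surface_cube_volume_within_voxel_shell():
    vox = np.zeros((14, 14, 14), dtype=np.uint8)
    vox[2:12, 2:12, 2:12] = 1  # 10x10x10 um cube at 1 um spacing
    mesh = ma.extract_surface(ma.ImageStack(vox, spacing=(1, 1, 1)))
    v = ma.mesh_volume(mesh)
    assert 9.0 ** 3 <= v <= 11.0 ** 3
    assert mesh.is_watertight()


def test_surface_sphere_volume_within_5pc():
    s = ball_stack(shape=(50, 50, 50), r=20.0, fg=1, bg=0)
    mesh = ma.extract_surface(ma.ImageStack(s.voxels, s.spacing))
    v = ma.mesh_volume(mesh)
    assert v == pytest.approx(4 / 3 * np.pi * 20 ** 3, rel=0.05)


def test_surface_empty_mask_is_error():
    with pytest.raises(AtlasError):
        ma.extract_surface(ma.ImageStack(np.zeros((4, 4, 4), dtype=np.uint8)))


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

def test_align_identity_when_already_in_frame():
    s = brain_blob()
    lms = blob_landmarks(s)
    out = ma.align_to_reference(s, lms, lms)
    assert dice(out.voxels > 100, s.voxels > 100) > 0.999


def test_align_recovers_rotated_blob(rng):
    s = brain_blob()
    lms = blob_landmarks(s)
    a = np.deg2rad(15.0)
    R = np.array([[np.cos(a), -np.sin(a), 0], [np.sin(a), np.cos(a), 0],
                  [0, 0, 1.0]])
    center = lms["CCB"]
    T = ma.RigidTransform(R, center - R @ center + [4.0, -2.0, 1.0])
    rotated = ma.resample_image(T, s)
    rotated_lms = lms.transformed(T.apply)
    back = ma.align_to_reference(rotated, rotated_lms, lms, reference=s)
    assert dice(back.voxels > 100, s.voxels > 100) >= 0.98


def test_align_requires_three_shared_names():
    s = brain_blob()
    two = ma.LandmarkSet.from_mapping({"CCB": (0, 0, 0), "RMC": (1, 1, 1)})
    with pytest.raises(Exception, match=">= 3"):
        ma.align_to_reference(s, two, two)


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def _jittered_samples(truth, lms, n, seed):
    """Rigidly jittered copies (half mirrored into 'left hemisphere' form)."""
    r = np.random.default_rng(seed)
    stacks, lm_sets, hemis = [], [], []
    for k in range(n):
        if k == 0:  # the reference stack stays in the truth frame
            stacks.append(truth)
            lm_sets.append(lms)
            hemis.append("R")
            continue
        a = np.deg2rad(r.uniform(-8, 8))
        axis = r.normal(size=3)
        axis /= np.linalg.norm(axis)
        K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]],
                      [-axis[1], axis[0], 0]])
        R = np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * (K @ K)
        center = lms["CCB"]
        t = center - R @ center + r.uniform(-4, 4, 3)
        T = ma.RigidTransform(R, t)
        sample = ma.resample_image(T, truth)
        sample_lms = lms.transformed(T.apply)
        if k % 2 == 1:  # express as a left hemisphere: mirror + relabel
            ext = sample.physical_extent()
            sample = ma.mirror(sample, "x")
            sample_lms = ma.swap_lr_names(
                ma.mirror(sample_lms, "x", extent=tuple(ext[0])))
            hemis.append("L")
        else:
            hemis.append("R")
        stacks.append(sample)
        lm_sets.append(sample_lms)
    return stacks, lm_sets, hemis


def test_build_standard_brain_recovers_shape():
    truth = brain_blob()
    lms = blob_landmarks(truth)
    stacks, lm_sets, hemis = _jittered_samples(truth, lms, 12, seed=5)
    cfg = AtlasConfig(stacks=stacks, landmarks=lm_sets, hemispheres=hemis)
    bundle = ma.build_standard_brain(cfg)
    truth_mask = ma.binarize_outline(truth).voxels
    assert dice(bundle.outline_mask.voxels, truth_mask) >= 0.95
    assert ma.mesh_volume(bundle.surface) > 0
    assert len(bundle.provenance) == 12


def test_build_single_input_average_equals_input():
    truth = brain_blob()
    lms = blob_landmarks(truth)
    cfg = AtlasConfig(stacks=[truth], landmarks=[lms], hemispheres=["R"])
    bundle = ma.build_standard_brain(cfg)
    np.testing.assert_allclose(bundle.average_stack.voxels, truth.voxels)


def test_build_from_identical_inputs_matches_single_input():
    truth = brain_blob()
    lms = blob_landmarks(truth)
    one = ma.build_standard_brain(
        AtlasConfig(stacks=[truth], landmarks=[lms], hemispheres=["R"]))
    three = ma.build_standard_brain(
        AtlasConfig(stacks=[truth] * 3, landmarks=[lms] * 3,
                    hemispheres=["R"] * 3))
    np.testing.assert_array_equal(one.outline_mask.voxels,
                                  three.outline_mask.voxels)


def test_build_validates_before_computation(tmp_path):
    cfg = AtlasConfig(stacks=[tmp_path / "missing.tif"],
                      landmarks=[tmp_path / "missing.csv"],
                      hemispheres=["R"])
    with pytest.raises(AtlasError, match="does not exist"):
        ma.build_standard_brain(cfg)


def test_bundle_save_round_trip(tmp_path):
    truth = brain_blob()
    lms = blob_landmarks(truth)
    bundle = ma.build_standard_brain(
        AtlasConfig(stacks=[truth], landmarks=[lms], hemispheres=["R"]))
    bundle.save(tmp_path / "bundle")
    assert (tmp_path / "bundle" / "average.tif").exists()
    assert (tmp_path / "bundle" / "surface.obj").exists()
    back = ma.read_stack(tmp_path / "bundle" / "outline_mask.tif")
    np.testing.assert_array_equal(back.voxels, bundle.outline_mask.voxels)
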