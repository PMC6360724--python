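"""Rigid pose estimation (Soderkvist-Wedin SVD) and CAST round-trips."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from footkin.rigidbody import (
    GeometryError,
    Pose,
    calibrate_local,
    estimate_pose,
    reconstruct_global,
)

TET = 70.0 / np.sqrt(3.0) * np.array(
    [[1.0, 1.0, 1.0], [1.0, -1.0, -1.0], [-1.0, 1.0, -1.0], [-1.0, -1.0, 1.0]]
)  # 70 mm-scale tetrahedron


def test_identity_on_equal_clouds():
    p = estimate_pose(TET, TET)
    np.testing.assert_allclose(p.rotation, np.eye(3), atol=1e-12)
    np.testing.assert_allclose(p.translation, 0.0, atol=1e-12)
    assert p.rms_residual <= 1e-9


def test_constructed_rotation_and_translation_recovered_exactly():
    R = Rotation.from_euler("z", 30.0, degrees=True).as_matrix()
    t = np.array([10.0, 0.0, 0.0])
    obs = TET @ R.T + t
    p = estimate_pose(TET, obs)
    np.testing.assert_allclose(p.rotation, R, atol=1e-9)
    np.testing.assert_allclose(p.translation, t, atol=1e-9)
    angle = np.degrees(
        np.arccos(np.clip((np.trace(p.rotation @ R.T) - 1) / 2, -1, 1))
    )
    assert angle < 1e-9
    assert p.rms_residual < 1e-9


def test_noise_free_exactness_over_random_transforms():
    rng = np.random.default_rng(0)
    for _ in range(50):
        R = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
        t = rng.normal(scale=500.0, size=3)
        p = estimate_pose(TET, TET @ R.T + t)
        np.testing.assert_allclose(p.rotation, R, atol=1e-9)
        assert p.rms_residual <= 1e-9


def test_monte_carlo_rotation_error_under_noise():
    """Median rotation error < 0.5 deg for a 70 mm-scale cluster at
    sigma = 0.5 mm over 1000 random transforms."""
    rng = np.random.default_rng(12345)
    errs = []
    for _ in range(1000):
        R = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
        t = rng.normal(scale=200.0, size=3)
        obs = TET @ R.T + t + rng.normal(0.0, 0.5, size=TET.shape)
        p = estimate_pose(TET, obs)
        errs.append(
            np.degrees(np.arccos(np.clip((np.trace(p.rotation @ R.T) - 1) / 2, -1, 1)))
        )
    assert np.median(errs) < 0.5


def test_agrees_with_scipy_align_vectors_oracle():
    """Independent cross-check against scipy's Kabsch implementation."""
    rng = np.random.default_rng(7)
    ref = rng.normal(scale=50.0, size=(6, 3))
    obs = ref @ Rotation.random(random_state=np.random.RandomState(3)).as_matrix().T
    obs = obs + np.array([5.0, -3.0, 8.0]) + rng.normal(0, 0.3, size=ref.shape)
    p = estimate_pose(ref, obs)
    rot, _ = Rotation.align_vectors(obs - obs.mean(0), ref - ref.mean(0))
    np.testing.assert_allclose(p.rotation, rot.as_matrix(), atol=1e-8)


def test_collinear_cloud_raises():
    line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]]) * 10
    with pytest.raises(GeometryError, match="collinear"):
        estimate_pose(line, line)


def test_mismatched_counts_raise():
    with pytest.raises(GeometryError):
        estimate_pose(TET, TET[:3])


def test_reflection_guard_returns_proper_rotation():
    """A reflected observation cloud must still give det(R) = +1."""
    obs = TET * np.array([1.0, 1.0, -1.0])
    p = estimate_pose(TET, obs)
    assert np.linalg.det(p.rotation) == pytest.approx(1.0, abs=1e-12)


def test_equivariance_under_lab_rotation():
    rng = np.random.default_rng(21)
    Q = Rotation.random(random_state=np.random.RandomState(5)).as_matrix()
    R = Rotation.random(random_state=np.random.RandomState(6)).as_matrix()
    t = rng.normal(size=3)
    obs = TET @ R.T + t
    p1 = estimate_pose(TET, obs)
    p2 = estimate_pose(TET @ Q.T, obs @ Q.T)
    np.testing.assert_allclose(p2.rotation, Q @ p1.rotation @ Q.T, atol=1e-9)


def test_cast_calibrate_reconstruct_identity():
    rng = np.random.default_rng(4)
    R = Rotation.random(random_state=np.random.RandomState(8)).as_matrix()
    pose = Pose(rotation=R, translation=rng.normal(scale=100, size=3))
    p = rng.normal(scale=80.0, size=3)
    local = calibrate_local(p, pose, owner="tibia")
    np.testing.assert_allclose(reconstruct_global(local, pose), p, atol=1e-9)


def test_cluster_origin_maps_to_zero_local():
    pose = Pose(rotation=np.eye(3), translation=np.array([10.0, 20.0, 30.0]))
    local = calibrate_local(np.array([10.0, 20.0, 30.0]), pose)
    np.testing.assert_allclose(local.coords, 0.0, atol=1e-12)


def test_cast_chain_tracks_rigid_motion_exactly():
    """Calibrate in one frame, reconstruct across noise-free rigid motion:
    error below 1e-6 mm."""
    rng = np.random.default_rng(10)
    anat = np.array([60.0, -20.0, 15.0])
    cal_pose = estimate_pose(TET, TET)
    local = calibrate_local(anat, cal_pose)
    for _ in range(20):
        R = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
        t = rng.normal(scale=300.0, size=3)
        pose = estimate_pose(TET, TET @ R.T + t)
        np.testing.assert_allclose(
            reconstruct_global(local, pose), R @ anat + t, atol=1e-6
        )


def test_noisy_reconstruction_error_bounded():
    rng = np.random.default_rng(31)
    anat = np.array([50.0, 10.0, -5.0])
    local = calibrate_local(anat, estimate_pose(TET, TET))
    errs = []
    for _ in range(500):
        R = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
        obs = TET @ R.T + rng.normal(0.0, 0.5, size=TET.shape)
        pose = estimate_pose(TET, obs)
        errs.append(np.linalg.norm(reconstruct_global(local, pose) - R @ anat))
    assert np.sqrt(np.mean(np.square(errs))) < 3 * 0.5
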