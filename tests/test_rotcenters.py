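"""Functional joint centre (SCoRE) and axis (SARA) recovery."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from footkin.rigidbody import GeometryError, Pose, estimate_pose
from footkin.rotcenters import AxisAmbiguityWarning, sara_axis, score_centre

CLUSTER_P = np.array(
    [[80.0, 0, 0], [0, 80, 0], [0, 0, 80], [50, 50, 50]]
)  # parent cluster, local
CLUSTER_C = CLUSTER_P + np.array([0.0, 0, -200])  # child cluster, local


def _poses_ball(centre, n=200, noise=0.0, seed=0, amp=40.0):
    """Parent static; child rotates about `centre` over a two-axis cone."""
    rng = np.random.default_rng(seed)
    t = np.linspace(0, 4 * np.pi, n)
    parent, child = [], []
    for k in range(n):
        Rr = Rotation.from_euler(
            "xyz", [amp * np.sin(t[k]), amp * np.cos(t[k]), 10.0], degrees=True
        ).as_matrix()
        # child cloud rigidly rotated about the centre
        obs_c = (CLUSTER_C - centre) @ Rr.T + centre
        obs_p = CLUSTER_P
        if noise:
            obs_c = obs_c + rng.normal(0, noise, obs_c.shape)
            obs_p = obs_p + rng.normal(0, noise, obs_p.shape)
        parent.append(estimate_pose(CLUSTER_P, obs_p))
        child.append(estimate_pose(CLUSTER_C, obs_c))
    return parent, child


def _poses_hinge(axis, point, n=200, arc=60.0, noise=0.0, seed=0, wobble=0.0):
    rng = np.random.default_rng(seed)
    angles = np.linspace(0, arc, n)
    axis = np.asarray(axis) / np.linalg.norm(axis)
    parent, child = [], []
    for k in range(n):
        Rr = Rotation.from_rotvec(np.radians(angles[k]) * axis).as_matrix()
        if wobble:
            w = Rotation.from_euler(
                "x", wobble * np.sin(7 * angles[k] / arc), degrees=True
            ).as_matrix()
            Rr = Rr @ w
        obs_c = (CLUSTER_C - point) @ Rr.T + point
        obs_p = CLUSTER_P
        if noise:
            obs_c = obs_c + rng.normal(0, noise, obs_c.shape)
            obs_p = obs_p + rng.normal(0, noise, obs_p.shape)
        parent.append(estimate_pose(CLUSTER_P, obs_p))
        child.append(estimate_pose(CLUSTER_C, obs_c))
    return parent, child


def test_score_exact_on_noise_free_ball_joint():
    centre = np.array([20.0, -30.0, -100.0])
    parent, child = _poses_ball(centre)
    fj = score_centre(parent, child)
    np.testing.assert_allclose(fj.centre_parent, centre, atol=1e-6)
    np.testing.assert_allclose(fj.centre_child, centre, atol=1e-6)
    assert fj.residual < 1e-6


def test_score_error_below_2mm_with_marker_noise():
    centre = np.array([20.0, -30.0, -100.0])
    parent, child = _poses_ball(centre, n=500, noise=0.5, seed=42)
    fj = score_centre(parent, child)
    assert np.linalg.norm(fj.centre_parent - centre) < 2.0
    assert np.linalg.norm(fj.centre_child - centre) < 2.0


def test_score_pure_translation_raises_conditioning_error():
    parent, child = [], []
    for k in range(50):
        shift = np.array([0.0, 0.0, -2.0 * k])
        parent.append(estimate_pose(CLUSTER_P, CLUSTER_P))
        child.append(estimate_pose(CLUSTER_C, CLUSTER_C + shift))
    with pytest.raises(GeometryError, match="unobservable"):
        score_centre(parent, child)


def test_score_too_few_frames_raises():
    parent, child = _poses_ball(np.zeros(3), n=5)
    with pytest.raises(GeometryError, match="frames"):
        score_centre(parent, child)


def test_sara_axis_exact_on_noise_free_hinge():
    axis = np.array([0.0, 1.0, 0.2])
    axis /= np.linalg.norm(axis)
    parent, child = _poses_hinge(axis, np.array([0.0, 0.0, -90.0]))
    fj = sara_axis(parent, child)
    err = np.degrees(np.arccos(np.clip(abs(fj.axis_parent @ axis), -1, 1)))
    assert err < 0.01
    err_c = np.degrees(np.arccos(np.clip(abs(fj.axis_child @ axis), -1, 1)))
    assert err_c < 0.01


def test_sara_axis_error_below_1deg_with_marker_noise():
    axis = np.array([0.1, 1.0, 0.0])
    axis /= np.linalg.norm(axis)
    parent, child = _poses_hinge(axis, np.array([0.0, 0.0, -90.0]), n=500, noise=0.5, seed=7)
    fj = sara_axis(parent, child)
    err = np.degrees(np.arccos(np.clip(abs(fj.axis_parent @ axis), -1, 1)))
    assert err < 1.0


def test_sara_residual_increases_with_wobble():
    axis = np.array([0.0, 1.0, 0.0])
    point = np.array([0.0, 0.0, -90.0])
    residuals = []
    for wob in (0.0, 1.0, 2.0, 4.0):
        parent, child = _poses_hinge(axis, point, wobble=wob)
        residuals.append(sara_axis(parent, child).residual)
    assert all(a < b for a, b in zip(residuals, residuals[1:]))


def test_sara_ball_motion_warns_ambiguous():
    parent, child = _poses_ball(np.array([0.0, 0.0, -100.0]))
    with pytest.warns(AxisAmbiguityWarning):
        sara_axis(parent, child)


def test_score_on_perfect_hinge_returns_point_on_axis():
    """The hinge leaves the centre free along the axis; the minimum-norm
    solution must still lie on the rotation axis."""
    axis = np.array([0.0, 1.0, 0.0])
    point = np.array([15.0, 0.0, -90.0])
    parent, child = _poses_hinge(axis, point)
    fj = score_centre(parent, child)
    sara = sara_axis(parent, child)
    # distance of SCoRE centre (parent frame) from the hinge line
    d = np.cross(fj.centre_parent - point, sara.axis_parent)
    assert np.linalg.norm(d) < 1e-6


def test_estimates_invariant_to_lab_rotation():
    centre = np.array([10.0, 5.0, -80.0])
    parent, child = _poses_ball(centre, n=150)
    Q = Rotation.from_euler("zyx", [30, 20, 10], degrees=True).as_matrix()
    shift = np.array([100.0, -50.0, 30.0])
    parent2 = [
        Pose(rotation=Q @ p.rotation, translation=Q @ p.translation + shift)
        for p in parent
    ]
    child2 = [
        Pose(rotation=Q @ p.rotation, translation=Q @ p.translation + shift)
        for p in child
    ]
    fj1 = score_centre(parent, child)
    fj2 = score_centre(parent2, child2)
    # local-frame centres are unchanged by a rigid lab re-expression
    np.testing.assert_allclose(fj1.centre_parent, fj2.centre_parent, atol=1e-8)
    np.testing.assert_allclose(fj1.centre_child, fj2.centre_child, atol=1e-8)
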