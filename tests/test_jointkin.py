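"""Cardan/JCS angle decomposition, sign conventions, and the first-MTPJ
transverse-plane angle."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from footkin.jointkin import (
    compose_jcs,
    foot_abduction,
    jcs_angles,
    jcs_angles_series,
    knee_transverse_angle,
    mtpj_transverse_angle,
    side_sign,
)
from footkin.rigidbody import GeometryError


def test_identical_frames_give_zero_angles():
    R = Rotation.from_euler("zyx", [40, -20, 10], degrees=True).as_matrix()
    assert jcs_angles(R, R) == pytest.approx((0.0, 0.0, 0.0), abs=1e-12)


def test_pure_third_axis_rotation_recovered_exactly():
    parent = np.eye(3)
    child = Rotation.from_euler("z", 10.0, degrees=True).as_matrix()
    a, b, c = jcs_angles(parent, child)  # sequence YXZ: z is the 3rd axis
    assert (a, b) == pytest.approx((0.0, 0.0), abs=1e-12)
    assert c == pytest.approx(10.0, abs=1e-9)


def test_cardan_round_trip_over_random_rotations():
    """decompose(compose) = identity within 1e-9 degrees over 1000 random
    rotations away from gimbal lock."""
    rng = np.random.default_rng(2024)
    count = 0
    while count < 1000:
        sag, fro, tra = rng.uniform(-179, 179), rng.uniform(-80, 80), rng.uniform(-179, 179)
        R = compose_jcs(sag, fro, tra)
        a, b, c = jcs_angles(np.eye(3), R)
        # recomposition reproduces the relative rotation matrix
        np.testing.assert_allclose(compose_jcs(a, b, c), R, atol=1e-9)
        count += 1


def test_gimbal_proximity_flagged():
    R = compose_jcs(10.0, 88.0, -5.0)
    with pytest.warns(RuntimeWarning, match="gimbal"):
        jcs_angles(np.eye(3), R)


def test_non_orthogonal_input_rejected():
    bad = np.eye(3) * 1.1
    with pytest.raises(GeometryError):
        jcs_angles(bad, np.eye(3))


def test_series_matches_scalar_decomposition():
    rng = np.random.default_rng(5)
    parents = Rotation.random(8, random_state=np.random.RandomState(1)).as_matrix()
    children = Rotation.random(8, random_state=np.random.RandomState(2)).as_matrix()
    series = jcs_angles_series(parents, children)
    for k in range(8):
        np.testing.assert_allclose(series[k], jcs_angles(parents[k], children[k]), atol=1e-12)


# --- first-MTPJ transverse angle -------------------------------------------

MT1 = np.array([150.0, 32.0, 28.0])
XMET = np.array([200.0, 32.0, 28.0])  # anterior of MT1 along +x
MET_R = np.eye(3)


def test_hal_on_metatarsal_axis_gives_zero():
    hal = MT1 + np.array([40.0, 0.0, 0.0])
    assert mtpj_transverse_angle(MT1, XMET, hal, MET_R, side="right") == pytest.approx(
        0.0, abs=1e-12
    )


@pytest.mark.parametrize("deg", [15.0, 20.0, 40.0])
def test_lateral_rotation_reads_positive_angle(deg):
    """A hallux rotated laterally in the transverse plane reads exactly
    that angle, positive (the hallux-valgus direction)."""
    lateral = np.radians(deg)
    # right side: lateral = -y
    hal = MT1 + 40.0 * np.array([np.cos(lateral), -np.sin(lateral), 0.0])
    assert mtpj_transverse_angle(MT1, XMET, hal, MET_R, side="right") == pytest.approx(
        deg, abs=1e-9
    )


def test_vertical_displacement_projected_out():
    hal = MT1 + np.array([40.0, 0.0, 25.0])
    assert mtpj_transverse_angle(MT1, XMET, hal, MET_R, side="right") == pytest.approx(
        0.0, abs=1e-12
    )


def test_hal_coincident_with_mt1_rejected():
    with pytest.raises(GeometryError, match="HAL"):
        mtpj_transverse_angle(MT1, XMET, MT1, MET_R)


def test_mtpj_invariant_under_rigid_motion():
    rng = np.random.default_rng(17)
    hal = MT1 + 40.0 * np.array([np.cos(0.3), -np.sin(0.3), 0.1])
    base = mtpj_transverse_angle(MT1, XMET, hal, MET_R, side="right")
    for _ in range(20):
        Q = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
        t = rng.normal(scale=300.0, size=3)
        moved = mtpj_transverse_angle(
            Q @ MT1 + t, Q @ XMET + t, Q @ hal + t, Q @ MET_R, side="right"
        )
        assert moved == pytest.approx(base, abs=1e-9)


def test_mirror_symmetry_of_sides():
    """The same anatomical deviation reads the same positive angle on a
    mirrored left foot."""
    lateral = np.radians(12.0)
    hal_r = MT1 + 40.0 * np.array([np.cos(lateral), -np.sin(lateral), 0.0])
    m = np.array([1.0, -1.0, 1.0])
    mirror = np.diag(m)
    hal_l, mt1_l, xmet_l = hal_r * m, MT1 * m, XMET * m
    met_l = mirror @ MET_R @ mirror  # mirrored frame (still right-handed here)
    r = mtpj_transverse_angle(MT1, XMET, hal_r, MET_R, side="right")
    l = mtpj_transverse_angle(mt1_l, xmet_l, hal_l, met_l, side="left")
    assert l == pytest.approx(r, abs=1e-9)


# --- named joint angles ------------------------------------------------------


def test_foot_abduction_sign_and_value():
    tibia = np.eye(3)
    for side, s in (("right", -1.0), ("left", 1.0)):
        foot = Rotation.from_euler("z", s * 12.0, degrees=True).as_matrix()
        assert foot_abduction(tibia, foot, side=side) == pytest.approx(12.0, abs=1e-9)


def test_knee_external_rotation_sign():
    thigh = np.eye(3)
    shank_ext = Rotation.from_euler("z", side_sign("right") * 20.0, degrees=True).as_matrix()
    assert knee_transverse_angle(thigh, shank_ext, side="right") == pytest.approx(
        20.0, abs=1e-9
    )
    shank_int = Rotation.from_euler("z", -side_sign("right") * 20.0, degrees=True).as_matrix()
    assert knee_transverse_angle(thigh, shank_int, side="right") == pytest.approx(
        -20.0, abs=1e-9
    )
    assert knee_transverse_angle(thigh, thigh, side="right") == pytest.approx(0.0, abs=1e-12)


def test_side_sign_validation():
    with pytest.raises(ValueError):
        side_sign("dorsal")
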