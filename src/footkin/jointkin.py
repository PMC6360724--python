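"""Joint-coordinate-system angles for the multi-segment foot model.

Anatomical frames follow one convention throughout the package: the x-axis
points anteriorly, the z-axis points along the segment's stance-calibrated
vertical, and y = z cross x completes a right-handed triad (so y points to
the laboratory left for either limb).  A joint rotation is the Cardan
decomposition of ``R_rel = R_parent.T @ R_child`` in an intrinsic
y-x-z sequence:

    R_rel = Ry(sagittal) @ Rx(frontal_raw) @ Rz(transverse_raw)

i.e. flexion/extension first, then the frontal-plane and transverse-plane
components.  Because the frames are built identically for left and right
limbs, the raw frontal/transverse components change sign between sides for
the same anatomical motion; :data:`side_sign` converts them to the
side-independent clinical conventions used in reporting:

* eversion positive (frontal plane),
* abduction / external rotation positive (transverse plane).

The first-MTPJ angle is not a segment-to-segment Cardan angle: it is the
signed angle, within the first metatarsal's transverse plane, between the
metatarsal's anterior axis (MTB1 to MT1, extended to the virtual point
X_MET) and the MT1-to-HAL direction, positive for lateral deviation of the
hallux (the hallux-valgus direction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .rigidbody import GeometryError

__all__ = [
    "AngleSeries",
    "side_sign",
    "jcs_angles",
    "jcs_angles_series",
    "compose_jcs",
    "mtpj_transverse_angle",
    "foot_abduction",
    "knee_transverse_angle",
    "GIMBAL_GUARD_DEG",
]

#: |frontal component| above which the Cardan decomposition is flagged as
#: close to gimbal lock.
GIMBAL_GUARD_DEG = 85.0

#: Default intrinsic Cardan sequence: sagittal, frontal, transverse.
DEFAULT_SEQUENCE = "YXZ"


def side_sign(side: str) -> float:
    """Sign mapping raw frontal/transverse Cardan components to clinical
    conventions (eversion/abduction/external rotation positive)."""
    if side == "right":
        return -1.0
    if side == "left":
        return 1.0
    raise ValueError(f"side must be 'right' or 'left', got {side!r}")


@dataclass
class AngleSeries:
    """A per-frame joint angle with its sign-convention metadata."""

    joint: str
    plane: str  # frontal | transverse | sagittal
    values: np.ndarray  # degrees per frame
    sign_convention: str

    def __post_init__(self) -> None:
        self.values = np.atleast_1d(np.asarray(self.values, dtype=float))
        if not self.sign_convention:
            raise ValueError("sign_convention must be non-empty")
        if not np.isfinite(self.values).all():
            raise ValueError("angle values must be finite")


def _check_rotation(R: np.ndarray, name: str) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.shape[-2:] != (3, 3):
        raise GeometryError(f"{name} must be 3x3 (or a stack of 3x3)")
    RTR = np.einsum("...ji,...jk->...ik", R, R)
    if not np.allclose(RTR, np.eye(3), atol=1e-6):
        raise GeometryError(f"{name} is not orthogonal")
    return R


def jcs_angles(
    parent: np.ndarray, child: np.ndarray, sequence: str = DEFAULT_SEQUENCE
) -> tuple[float, float, float]:
    """Cardan angles (degrees) of the child frame relative to the parent.

    Returns the intrinsic-sequence components in sequence order; for the
    default ``YXZ`` that is (sagittal, frontal_raw, transverse_raw).  The
    middle (second-axis) component is checked against the gimbal guard.
    """
    a = jcs_angles_series(parent[None], child[None], sequence)[0]
    return float(a[0]), float(a[1]), float(a[2])


def jcs_angles_series(
    parent: np.ndarray, child: np.ndarray, sequence: str = DEFAULT_SEQUENCE
) -> np.ndarray:
    """Vectorised :func:`jcs_angles` over stacks of frames, shape (F, 3)."""
    parent = _check_rotation(parent, "parent")
    child = _check_rotation(child, "child")
    rel = np.einsum("...ji,...jk->...ik", parent, child)
    ang = Rotation.from_matrix(rel).as_euler(sequence, degrees=True)
    ang = np.atleast_2d(ang)
    if np.any(np.abs(ang[:, 1]) > GIMBAL_GUARD_DEG):
        import warnings

        warnings.warn("Cardan decomposition near gimbal lock", RuntimeWarning, stacklevel=2)
    return ang


def compose_jcs(
    sagittal: float | np.ndarray,
    frontal: float | np.ndarray,
    transverse: float | np.ndarray,
    sequence: str = DEFAULT_SEQUENCE,
) -> np.ndarray:
    """Inverse of :func:`jcs_angles`: build ``R_rel`` from raw Cardan
    components in degrees.  Accepts scalars or equal-length arrays (then
    returns a stack of matrices)."""
    s, f, t = np.broadcast_arrays(
        np.atleast_1d(sagittal), np.atleast_1d(frontal), np.atleast_1d(transverse)
    )
    angles = {"Y": s, "X": f, "Z": t}
    cols = np.stack([angles[ax.upper()] for ax in sequence], axis=-1)
    R = Rotation.from_euler(sequence, cols, degrees=True).as_matrix()
    return R if R.shape[0] > 1 else R[0]


def _project_transverse(v: np.ndarray, vertical: np.ndarray) -> np.ndarray:
    return v - np.einsum("...i,...i->...", v, vertical)[..., None] * vertical


def mtpj_transverse_angle(
    MT1: np.ndarray,
    X_MET: np.ndarray,
    HAL: np.ndarray,
    met_rotation: np.ndarray,
    side: str = "right",
) -> np.ndarray:
    """First-MTPJ transverse-plane angle, degrees, positive = lateral
    deviation of the hallux (abduction in the hallux-valgus sense).

    ``MT1``, ``X_MET`` and ``HAL`` are laboratory positions (frames x 3 or
    a single point); ``met_rotation`` is the first-metatarsal anatomical
    rotation (its third column is the transverse-plane normal).
    """
    MT1 = np.atleast_2d(np.asarray(MT1, dtype=float))
    X_MET = np.atleast_2d(np.asarray(X_MET, dtype=float))
    HAL = np.atleast_2d(np.asarray(HAL, dtype=float))
    R = np.asarray(met_rotation, dtype=float)
    if R.ndim == 2:
        R = np.broadcast_to(R, (MT1.shape[0], 3, 3))
    vertical = R[..., :, 2]
    u = HAL - MT1
    if np.any(np.linalg.norm(u, axis=-1) < 1e-9):
        raise GeometryError("HAL coincides with MT1: MTPJ angle undefined")
    v = X_MET - MT1
    u = _project_transverse(u, vertical)
    v = _project_transverse(v, vertical)
    cross = np.cross(v, u)
    sin = np.einsum("...i,...i->...", cross, vertical)
    cos = np.einsum("...i,...i->...", v, u)
    ang = np.degrees(np.arctan2(sin, cos)) * side_sign(side)
    return ang if ang.shape[0] > 1 else ang[:1].reshape(())


def foot_abduction(
    tibia_rotation: np.ndarray, foot_rotation: np.ndarray, side: str = "right"
) -> np.ndarray:
    """Transverse-plane angle of the whole foot relative to the tibia
    (TIB-FOOT), degrees, abduction (toe-out) positive."""
    ang = jcs_angles_series(
        np.asarray(tibia_rotation, dtype=float).reshape(-1, 3, 3),
        np.asarray(foot_rotation, dtype=float).reshape(-1, 3, 3),
    )
    out = ang[:, 2] * side_sign(side)
    return out if out.shape[0] > 1 else out.reshape(())


def knee_transverse_angle(
    thigh_rotation: np.ndarray,
    shank_rotation: np.ndarray,
    side: str = "right",
) -> np.ndarray:
    """Transverse-plane knee angle, degrees, external tibiofemoral rotation
    positive.  The thigh and shank frames must be the functional knee
    frames (built around the knee joint centre and the functional flexion
    axis during calibration)."""
    ang = jcs_angles_series(
        np.asarray(thigh_rotation, dtype=float).reshape(-1, 3, 3),
        np.asarray(shank_rotation, dtype=float).reshape(-1, 3, 3),
    )
    out = ang[:, 2] * side_sign(side)
    return out if out.shape[0] > 1 else out.reshape(())
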