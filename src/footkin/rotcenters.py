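"""Functional joint centre (SCoRE) and axis (SARA) estimation.

Both methods use only the relative motion of two tracked segments, with no
anatomical assumptions.  SCoRE finds the pair of points — one fixed in the
parent's technical frame, one in the child's — whose global positions stay
as close as possible over the trial, by solving one stacked linear
least-squares system:

    R_p(t) c_p + t_p(t) = R_c(t) c_c + t_c(t)   for all frames t.

The joint centre is fixed under rotation about *any* axis, so the movement
must rotate about at least two directions (e.g. hip circumduction); a
hinge-only record leaves the centre unconstrained along the hinge axis and
is reported as a conditioning error.

SARA estimates a hinge axis: the direction in each segment frame that is
invariant under the relative rotation.  Stacking ``R_p(t) a_p - R_c(t) a_c
= 0`` over frames and taking the SVD of the 3F x 6 system yields the axis
pair as the right singular vector of the smallest singular value.  A
ball-like record (no dominant axis) makes the two smallest singular values
comparable and is flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np

from .rigidbody import GeometryError, Pose

__all__ = ["FunctionalJoint", "AxisAmbiguityWarning", "score_centre", "sara_axis"]


class AxisAmbiguityWarning(UserWarning):
    """Relative motion is ball-like; the hinge axis is poorly defined."""


@dataclass
class FunctionalJoint:
    """Functional calibration result for one joint.

    ``centre_parent``/``centre_child`` are SCoRE centres in each segment's
    technical frame (mm); ``axis_parent``/``axis_child`` are SARA unit axes.
    Fields not produced by the method that built the object are None.
    ``residual`` is the RMS of the stacked least-squares equations (mm for
    SCoRE, dimensionless rotation misfit for SARA).
    """

    centre_parent: np.ndarray | None = None
    centre_child: np.ndarray | None = None
    axis_parent: np.ndarray | None = None
    axis_child: np.ndarray | None = None
    residual: float = 0.0
    condition_number: float = np.inf

    def centre_global(self, parent_pose: Pose, child_pose: Pose) -> np.ndarray:
        """Joint centre in lab coordinates, averaged over the two segments."""
        if self.centre_parent is None or self.centre_child is None:
            raise ValueError("no SCoRE centres on this joint")
        return 0.5 * (parent_pose.apply(self.centre_parent) + child_pose.apply(self.centre_child))


def _stack_poses(poses: list[Pose]) -> tuple[np.ndarray, np.ndarray]:
    R = np.stack([p.rotation for p in poses])
    t = np.stack([p.translation for p in poses])
    return R, t


def _rotation_range(R_rel: np.ndarray) -> float:
    """Largest relative rotation angle (degrees) across the frame set."""
    angles = []
    for i in (0, len(R_rel) // 2):
        base = R_rel[i]
        tr = np.einsum("ij,fij->f", base, R_rel)
        angles.append(np.degrees(np.arccos(np.clip((tr - 1) / 2, -1, 1))).max())
    return float(max(angles))


def score_centre(
    parent_poses: list[Pose],
    child_poses: list[Pose],
    min_frames: int = 10,
    max_condition: float = 1e6,
) -> FunctionalJoint:
    """Symmetrical centre-of-rotation estimation from two pose sequences.

    A hinge-only record leaves the centre undetermined along one direction
    (the hinge axis); the minimum-norm least-squares solution is returned,
    which lies on the axis.

    Raises
    ------
    GeometryError
        Fewer than ``min_frames`` frames, or relative motion that leaves
        the centre unobservable in two or more directions (e.g. pure
        translation).
    """
    if len(parent_poses) != len(child_poses):
        raise GeometryError("pose sequences differ in length")
    if len(parent_poses) < min_frames:
        raise GeometryError(f"need >= {min_frames} frames, got {len(parent_poses)}")
    Rp, tp = _stack_poses(parent_poses)
    Rc, tc = _stack_poses(child_poses)
    F = len(parent_poses)
    A = np.zeros((3 * F, 6))
    A[:, :3] = Rp.reshape(3 * F, 3)
    A[:, 3:] = -Rc.reshape(3 * F, 3)
    b = (tc - tp).reshape(3 * F)
    sol, _res, _rank, sv = np.linalg.lstsq(A, b, rcond=1.0 / max_condition)
    cond = float(sv[0] / sv[-1]) if sv[-1] > 0 else np.inf
    # >= 2 near-null directions: no point is even direction-wise observable
    if sv[-2] < sv[0] / max_condition:
        raise GeometryError(
            f"relative motion leaves the centre unobservable (condition number {cond:.3g})"
        )
    resid = A @ sol - b
    rms = float(np.sqrt(np.mean(np.sum(resid.reshape(F, 3) ** 2, axis=1))))
    return FunctionalJoint(
        centre_parent=sol[:3], centre_child=sol[3:], residual=rms, condition_number=cond
    )


def sara_axis(
    parent_poses: list[Pose],
    child_poses: list[Pose],
    min_frames: int = 10,
    ambiguity_ratio: float = 4.0,
) -> FunctionalJoint:
    """Symmetrical axis-of-rotation estimation for a hinge-dominant joint.

    The axis sign is chosen so that ``axis_child`` has a positive component
    along the child frame's second (mediolateral) technical axis, a fixed
    distal-to-proximal convention; callers re-orient per side as needed.

    Warns
    -----
    AxisAmbiguityWarning
        When the two smallest singular values of the stacked system are
        within ``ambiguity_ratio`` of each other (ball-like motion).
    """
    if len(parent_poses) != len(child_poses):
        raise GeometryError("pose sequences differ in length")
    if len(parent_poses) < min_frames:
        raise GeometryError(f"need >= {min_frames} frames, got {len(parent_poses)}")
    Rp, _tp = _stack_poses(parent_poses)
    Rc, _tc = _stack_poses(child_poses)
    F = len(Rp)
    A = np.zeros((3 * F, 6))
    A[:, :3] = Rp.reshape(3 * F, 3)
    A[:, 3:] = -Rc.reshape(3 * F, 3)
    _U, s, Vt = np.linalg.svd(A, full_matrices=False)
    # the hinge-axis pair lives in the null direction; a genuine hinge has
    # exactly one near-zero singular value
    if s[-2] < ambiguity_ratio * max(s[-1], 1e-15):
        warnings.warn(
            "two comparable small singular values: ball-like motion, axis ambiguous",
            AxisAmbiguityWarning,
            stacklevel=2,
        )
    v = Vt[-1]
    ap, ac = v[:3], v[3:]
    np_, nc = np.linalg.norm(ap), np.linalg.norm(ac)
    if np_ < 1e-12 or nc < 1e-12:
        raise GeometryError("degenerate axis solution")
    ap, ac = ap / np_, ac / nc
    if ac[1] < 0:
        ap, ac = -ap, -ac
    resid = float(s[-1] / np.sqrt(F))
    return FunctionalJoint(
        axis_parent=ap,
        axis_child=ac,
        residual=resid,
        condition_number=float(s[0] / s[-1]) if s[-1] > 0 else np.inf,
    )
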