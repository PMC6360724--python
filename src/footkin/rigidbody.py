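"""Least-squares rigid pose estimation and CAST virtual-marker reconstruction.

A segment's technical frame is tracked by a cluster of three or more
markers.  The pose of the cluster in any frame is the proper rigid
transform (R, t) minimising the sum of squared distances to the observed
marker positions — the Soderkvist–Wedin SVD solution, with the reflection
guard that flips the smallest singular direction when the raw solution has
det(R) = -1.

The calibrated anatomical system technique (CAST) stores an anatomical
landmark's position in the cluster's technical frame during a calibration
trial (``calibrate_local``) and maps it back to laboratory coordinates in
any other frame of any trial (``reconstruct_global``).  On noise-free rigid
motion the chain is exact to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Pose",
    "LocalPoint",
    "GeometryError",
    "estimate_pose",
    "estimate_pose_series",
    "calibrate_local",
    "reconstruct_global",
]


class GeometryError(ValueError):
    """Degenerate geometry: collinear cluster, mismatched clouds, bad pose."""


@dataclass
class Pose:
    """Rigid transform of a marker cluster: ``x_global = R @ x_local + t``.

    ``rms_residual`` is the RMS marker misfit of the least-squares
    solution (mm); zero, up to rounding, for noise-free rigid motion.
    """

    rotation: np.ndarray
    translation: np.ndarray
    rms_residual: float = 0.0

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if self.rotation.shape != (3, 3):
            raise GeometryError("rotation must be 3x3")
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-8):
            raise GeometryError("rotation is not orthogonal")
        if np.linalg.det(self.rotation) < 0:
            raise GeometryError("rotation is a reflection (det = -1)")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation

    def invert(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points) - self.translation) @ self.rotation


@dataclass
class LocalPoint:
    """A point expressed in the technical frame of its owning segment."""

    owner_segment: str
    coords: np.ndarray
    source_trial: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(3)
        if not np.isfinite(self.coords).all():
            raise ValueError("local coordinates must be finite")


def _check_cloud(ref: np.ndarray, obs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.asarray(ref, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if ref.shape != obs.shape:
        raise GeometryError(f"cloud shapes differ: {ref.shape} vs {obs.shape}")
    if ref.ndim != 2 or ref.shape[1] != 3 or ref.shape[0] < 3:
        raise GeometryError("need >= 3 matched 3D points")
    centred = ref - ref.mean(axis=0)
    # rank >= 2 means the points span a plane (non-collinear)
    s = np.linalg.svd(centred, compute_uv=False)
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise GeometryError("reference cloud is collinear")
    return ref, obs


def estimate_pose(ref_cloud: np.ndarray, obs_cloud: np.ndarray) -> Pose:
    """Optimal rigid transform mapping ``ref_cloud`` onto ``obs_cloud``.

    Minimises ``sum_i ||obs_i - (R @ ref_i + t)||^2`` over proper rotations
    (Soderkvist–Wedin).  Marker weights are uniform.

    Raises
    ------
    GeometryError
        For collinear reference clouds or mismatched point counts.
    """
    ref, obs = _check_cloud(ref_cloud, obs_cloud)
    rc, oc = ref.mean(axis=0), obs.mean(axis=0)
    H = (ref - rc).T @ (obs - oc)
    U, _s, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = oc - R @ rc
    resid = obs - (ref @ R.T + t)
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return Pose(rotation=R, translation=t, rms_residual=rms)


def estimate_pose_series(ref_cloud: np.ndarray, obs_series: np.ndarray) -> list[Pose]:
    """Pose per frame for ``obs_series`` of shape (n_frames, n_markers, 3)."""
    return [estimate_pose(ref_cloud, obs) for obs in np.asarray(obs_series, dtype=float)]


def calibrate_local(
    anatomical_point: np.ndarray, cluster_pose: Pose, owner: str = "", trial: str = ""
) -> LocalPoint:
    """Express a global anatomical point in the cluster's technical frame.

    ``coords = R.T @ (p - t)`` so that ``reconstruct_global`` with the same
    pose returns ``p`` exactly.
    """
    p = np.asarray(anatomical_point, dtype=float).reshape(3)
    return LocalPoint(owner_segment=owner, coords=cluster_pose.invert(p), source_trial=trial)


def reconstruct_global(local: LocalPoint, cluster_pose: Pose) -> np.ndarray:
    """Map a calibrated local point back to laboratory coordinates."""
    return cluster_pose.apply(local.coords)
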