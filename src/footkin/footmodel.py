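"""Anatomical coordinate systems for the multi-segment foot model.

The model carries seven segment frames: pelvis, thigh, shank (functional
knee frame), tibia (malleolar ankle frame), hindfoot, midfoot, forefoot,
first metatarsal, and a whole-foot frame, plus the virtual points used by
the angle definitions (malleoli, CALe, MT1, KJC, MidMet, FTML, X_MET).

Calibration is anchored in the natural double-leg upright stance trial:

1.  Each segment's *technical* frame is defined by its tracked marker
    cluster; the cluster's stance-mean geometry is the reference cloud, so
    the stance pose of every cluster is the identity and any later pose is
    the rigid least-squares transform from stance.
2.  Calibration-only markers (malleoli, MT1, CALe, femoral epicondyles)
    are stored as local points in their owning cluster's technical frame
    (CAST) and reconstructed in every other trial.
3.  Each anatomical frame is built once, in stance, from anatomical and
    virtual points: the segment's anterior line is projected onto the
    horizontal plane, the vertical axis is the laboratory up-axis, and
    y = z cross x.  The constant rotation from the technical frame to this
    anatomical frame is then carried through every trial, so angles are
    absolute (a segment held away from neutral reads a non-zero angle in
    every condition, including natural stance).

The knee uses dedicated functional frames: origin at the knee joint centre
(midpoint of the lunge-calibrated femoral epicondyles) and mediolateral
direction from the SARA flexion axis, for both thigh and shank.

The whole-foot frame spans segments (heel offset CALe to the forefoot
midpoint FTML) and is therefore rebuilt per frame from the reconstructed
points, with the hindfoot vertical as the transverse reference and a
constant stance-snapshot correction so that its vertical axis is exactly
the laboratory up-axis in the calibration trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .markerio import MarkerSchema, Trial
from .rigidbody import (
    GeometryError,
    LocalPoint,
    Pose,
    calibrate_local,
    estimate_pose,
    reconstruct_global,
)
from .rotcenters import FunctionalJoint

__all__ = [
    "Calibration",
    "SegmentFrameSet",
    "VirtualPoints",
    "CalibrationError",
    "GapError",
    "calibrate_stance",
    "calibrate_knee",
    "calibrate_functional",
    "build_frames",
    "X_MET_LENGTH_MM",
]

#: Length of the anterior metatarsal axis used to place the X_MET virtual
#: marker beyond MT1 (mm).  Only the direction matters for the MTPJ angle.
X_MET_LENGTH_MM = 50.0


class CalibrationError(ValueError):
    """A required calibration trial, marker, or local point is missing."""


class GapError(ValueError):
    """A marker needed for a requested output has flagged gaps."""


@dataclass
class Calibration:
    """Subject calibration bundle built from the static/functional trials."""

    side: str
    up: int  # lab vertical axis index
    tech_ref: dict[str, tuple[list[str], np.ndarray]] = field(default_factory=dict)
    local_points: dict[str, LocalPoint] = field(default_factory=dict)
    anat_local_R: dict[str, np.ndarray] = field(default_factory=dict)
    anat_local_o: dict[str, np.ndarray] = field(default_factory=dict)
    knee: FunctionalJoint | None = None  # SARA flexion axis
    hip: FunctionalJoint | None = None  # SCoRE centre
    xmet_length: float = X_MET_LENGTH_MM

    def require_point(self, name: str) -> LocalPoint:
        if name not in self.local_points:
            raise CalibrationError(f"missing calibrated point {name!r}")
        return self.local_points[name]


@dataclass
class SegmentFrameSet:
    """Per-frame anatomical frames: name -> (origins (F,3), rotations (F,3,3))."""

    origins: dict[str, np.ndarray]
    rotations: dict[str, np.ndarray]
    provenance: dict[str, str] = field(default_factory=dict)

    def n_frames(self) -> int:
        return next(iter(self.origins.values())).shape[0]


@dataclass
class VirtualPoints:
    """Reconstructed virtual-marker trajectories, name -> (F, 3) mm."""

    points: dict[str, np.ndarray]

    def __getitem__(self, name: str) -> np.ndarray:
        return self.points[name]

    def __contains__(self, name: str) -> bool:
        return name in self.points


def _up_vector(up: int) -> np.ndarray:
    e = np.zeros(3)
    e[up] = 1.0
    return e


def _horizontal(v: np.ndarray, up: int) -> np.ndarray:
    h = np.array(v, dtype=float)
    h[up] = 0.0
    n = np.linalg.norm(h)
    if n < 1e-9:
        raise GeometryError("anterior line is vertical: cannot project to horizontal")
    return h / n


def _stance_frame_from_anterior(anterior: np.ndarray, up: int) -> np.ndarray:
    """Right-handed frame with x = horizontal projection of ``anterior``
    and z = lab up.  Columns are the axes."""
    x = _horizontal(anterior, up)
    z = _up_vector(up)
    y = np.cross(z, x)
    return np.column_stack([x, y, z])


def _stance_frame_from_mediolateral(lat_to_med: np.ndarray, up: int, side: str) -> np.ndarray:
    """Frame whose anterior axis is horizontal and perpendicular to a
    lateral-to-medial marker line (used for the tibia, whose markers give a
    mediolateral rather than an anterior line)."""
    m = _horizontal(lat_to_med, up)
    z = _up_vector(up)
    x = np.cross(m, z) if side == "right" else np.cross(z, m)
    x /= np.linalg.norm(x)
    y = np.cross(z, x)
    return np.column_stack([x, y, z])


def _mean_positions(trial: Trial, names: list[str]) -> dict[str, np.ndarray]:
    out = {}
    for n in names:
        if not trial.has(n):
            raise CalibrationError(f"calibration trial lacks marker {n!r}")
        i = trial.markers.index(n)
        if trial.gaps[:, i].any():
            raise GapError(f"gaps in calibration marker {n!r}")
        out[n] = trial.data[:, i].mean(axis=0)
    return out


def cluster_pose(trial_or_obs, calibration: Calibration, segment: str, frame=None):
    """Pose of one segment's cluster: in one frame, or per frame (list)."""
    names, ref = calibration.tech_ref[segment]
    if isinstance(trial_or_obs, Trial):
        idx = [trial_or_obs.markers.index(n) for n in names]
        obs = trial_or_obs.data[:, idx]
        if frame is not None:
            return estimate_pose(ref, obs[frame])
        return [estimate_pose(ref, o) for o in obs]
    return estimate_pose(ref, np.asarray(trial_or_obs))


def calibrate_stance(stance: Trial, schema: MarkerSchema) -> Calibration:
    """Build the calibration bundle from the natural-stance trial.

    Defines every segment's technical reference cloud, stores the
    calibration-only points in their owners' technical frames, and
    snapshots every anatomical frame recipe (stance verticals = lab up).
    """
    up = stance.up_index
    cal = Calibration(side=stance.side, up=up)

    # technical reference clouds = stance-mean cluster geometry
    for seg in schema.segments:
        tech = schema.technical(seg)
        if len(tech) < 3:
            continue  # single-marker segments (hallux) carry no frame
        if not all(stance.has(n) for n in tech):
            continue  # cluster not captured in this stance trial
        pos = _mean_positions(stance, tech)
        cal.tech_ref[seg] = (tech, np.stack([pos[n] for n in tech]))

    # stance poses are the identity by construction; local coordinates of
    # any stance point in a cluster frame are simply its stance position
    p = _mean_positions(
        stance,
        ["LMAL", "MMAL", "CAL", "SUS", "HDL", "CALe", "MFM", "CUB", "MFD",
         "MT2", "MT5", "MTB2", "MTB1", "MTS1", "MTS2", "MT1"],
    )
    for name, owner in (("LMAL", "tibia"), ("MMAL", "tibia"),
                        ("CALe", "hindfoot"), ("MT1", "first_metatarsal")):
        cal.local_points[name] = LocalPoint(owner_segment=owner, coords=p[name],
                                            source_trial=stance.label)

    side = stance.side
    recipes: dict[str, tuple[np.ndarray, np.ndarray, str]] = {}
    recipes["tibia"] = (
        0.5 * (p["LMAL"] + p["MMAL"]),
        _stance_frame_from_mediolateral(p["MMAL"] - p["LMAL"], up, side),
        "origin mid-malleoli; mediolateral axis LMAL->MMAL",
    )
    recipes["hindfoot"] = (
        p["CAL"],
        _stance_frame_from_anterior(p["CALe"] - p["CAL"], up),
        "origin CAL; anterior axis CAL->CALe",
    )
    mid_nc = 0.5 * (p["MFM"] + p["CUB"])
    recipes["midfoot"] = (
        mid_nc,
        _stance_frame_from_anterior(p["MFD"] - mid_nc, up),
        "origin mid(MFM,CUB); anterior axis toward MFD",
    )
    recipes["forefoot"] = (
        p["MTB2"],
        _stance_frame_from_anterior(p["MT2"] - p["MTB2"], up),
        "origin MTB2; anterior axis MTB2->MT2",
    )
    recipes["first_metatarsal"] = (
        p["MT1"],
        _stance_frame_from_anterior(p["MT1"] - p["MTB1"], up),
        "origin MT1; anterior axis MTB1->MT1",
    )
    ftml = 0.5 * (p["MT1"] + p["MT5"])
    recipes["foot"] = (
        p["CALe"],
        _stance_frame_from_anterior(ftml - p["CALe"], up),
        "origin CALe; anterior axis CALe->FTML, horizontal in stance",
    )
    if "pelvis" in cal.tech_ref:
        _, ref = cal.tech_ref["pelvis"]
        recipes["pelvis"] = (ref.mean(axis=0), np.eye(3), "cluster centroid; stance-aligned")

    carriers = {"foot": "hindfoot", "pelvis": "pelvis"}
    for name, (origin, R, prov) in recipes.items():
        carrier = carriers.get(name, name)
        if carrier not in cal.tech_ref:
            raise CalibrationError(f"no technical cluster for segment {carrier!r}")
        # stance cluster pose is the identity, so the local rotation equals
        # the stance anatomical rotation and the local origin the stance origin
        cal.anat_local_R[name] = R
        cal.anat_local_o[name] = origin
    return cal


def calibrate_knee(lunge: Trial, calibration: Calibration) -> Calibration:
    """Store the femoral epicondyles in the thigh technical frame and
    derive the knee joint centre (their midpoint) from the lunge trial."""
    if "thigh" not in calibration.tech_ref:
        raise CalibrationError("stance calibration with a thigh cluster required first")
    p = _mean_positions(lunge, ["LEP", "MEP"])
    poses = cluster_pose(lunge, calibration, "thigh")
    mean_pose = poses[len(poses) // 2]
    for name in ("LEP", "MEP"):
        calibration.local_points[name] = calibrate_local(
            p[name], mean_pose, owner="thigh", trial=lunge.label
        )
    kjc = 0.5 * (calibration.local_points["LEP"].coords + calibration.local_points["MEP"].coords)
    calibration.local_points["KJC"] = LocalPoint(
        owner_segment="thigh", coords=kjc, source_trial=lunge.label
    )
    return calibration


def calibrate_functional(squat_circ: Trial, calibration: Calibration) -> Calibration:
    """SARA knee axis (thigh-shank) and SCoRE hip centre (pelvis-thigh)
    from the squat + hip-circumduction trial, then build the functional
    knee frames for the thigh and shank."""
    from .rotcenters import sara_axis, score_centre

    for seg in ("pelvis", "thigh", "tibia"):
        if seg not in calibration.tech_ref:
            raise CalibrationError(f"stance calibration lacks the {seg} cluster")
    pelvis = cluster_pose(squat_circ, calibration, "pelvis")
    thigh = cluster_pose(squat_circ, calibration, "thigh")
    shank = cluster_pose(squat_circ, calibration, "tibia")
    calibration.knee = sara_axis(thigh, shank)
    calibration.hip = score_centre(pelvis, thigh)

    if "KJC" not in calibration.local_points:
        raise CalibrationError("knee joint centre (KJC) not calibrated: lunge trial required")
    up = calibration.up
    side = calibration.side
    # SARA axes are expressed in the technical frames, which coincide with
    # the stance laboratory frame; orient them lateral-to-medial like the
    # malleolar line (medial = +y for right, -y for left in this convention)
    med = np.zeros(3)
    med[(up + 2) % 3] = 1.0 if side == "right" else -1.0  # lab y for z-up

    def knee_frame(axis: np.ndarray) -> np.ndarray:
        a = axis if float(axis @ med) >= 0 else -axis
        return _stance_frame_from_mediolateral(a, up, side)

    calibration.anat_local_R["thigh"] = knee_frame(calibration.knee.axis_parent)
    calibration.anat_local_R["shank"] = knee_frame(calibration.knee.axis_child)
    # thigh origin: KJC (local in thigh technical frame); shank shares the
    # tibia cluster, with the stance KJC as a nominal origin
    thigh_stance_pose = Pose(rotation=np.eye(3), translation=np.zeros(3))
    kjc_stance = reconstruct_global(calibration.local_points["KJC"], thigh_stance_pose)
    calibration.anat_local_o["thigh"] = kjc_stance
    calibration.anat_local_o["shank"] = kjc_stance
    return calibration


def _require_no_gaps(trial: Trial, names: list[str], context: str) -> None:
    for n in names:
        if trial.has(n):
            i = trial.markers.index(n)
            if trial.gaps[:, i].any():
                raise GapError(f"gaps in marker {n!r} required for {context}")


def build_frames(
    trial: Trial, schema: MarkerSchema, calibration: Calibration
) -> tuple[SegmentFrameSet, VirtualPoints]:
    """Reconstruct virtual points and anatomical frames for every frame of
    a (validated, optionally filtered) trial.

    Segments whose clusters are absent from the trial are skipped; angle
    computation downstream raises if a needed frame is missing.
    """
    F = trial.n_frames
    poses: dict[str, list[Pose]] = {}
    for seg, (names, _ref) in calibration.tech_ref.items():
        if all(trial.has(n) for n in names):
            _require_no_gaps(trial, names, f"{seg} cluster")
            poses[seg] = cluster_pose(trial, calibration, seg)

    def recon(point: str) -> np.ndarray:
        lp = calibration.require_point(point)
        if lp.owner_segment not in poses:
            raise CalibrationError(
                f"cannot reconstruct {point!r}: no {lp.owner_segment} cluster in trial"
            )
        return np.stack([reconstruct_global(lp, p) for p in poses[lp.owner_segment]])

    virtuals: dict[str, np.ndarray] = {}
    if "tibia" in poses:
        virtuals["LMAL"] = recon("LMAL")
        virtuals["MMAL"] = recon("MMAL")
    if "hindfoot" in poses:
        virtuals["CALe"] = recon("CALe")
    if "first_metatarsal" in poses:
        virtuals["MT1"] = recon("MT1")
    if "thigh" in poses and "KJC" in calibration.local_points:
        virtuals["KJC"] = recon("KJC")

    origins: dict[str, np.ndarray] = {}
    rotations: dict[str, np.ndarray] = {}
    provenance: dict[str, str] = {}

    carriers = {"foot": "hindfoot", "shank": "tibia"}
    for name, R_local in calibration.anat_local_R.items():
        carrier = carriers.get(name, name)
        if carrier not in poses or name == "foot":
            continue
        o_local = calibration.anat_local_o[name]
        seg_poses = poses[carrier]
        rotations[name] = np.stack([p.rotation @ R_local for p in seg_poses])
        origins[name] = np.stack([p.apply(o_local) for p in seg_poses])
        provenance[name] = f"carried by {carrier} cluster (stance snapshot)"

    # derived virtual points
    if "first_metatarsal" in poses and trial.has("MTB1"):
        mtb1 = trial.get("MTB1")
        virtuals["MidMet"] = 0.5 * (mtb1 + virtuals["MT1"])
        x_met = rotations["first_metatarsal"][:, :, 0]
        virtuals["X_MET"] = virtuals["MT1"] + calibration.xmet_length * x_met
    if "MT1" in virtuals and trial.has("MT5"):
        _require_no_gaps(trial, ["MT5"], "FTML")
        virtuals["FTML"] = 0.5 * (virtuals["MT1"] + trial.get("MT5"))

    # whole-foot frame: rebuilt per frame from CALe->FTML with the hindfoot
    # vertical as transverse reference, then stance-corrected
    if "foot" in calibration.anat_local_R and "CALe" in virtuals and "FTML" in virtuals:
        z_ref = rotations["hindfoot"][:, :, 2]
        x_raw = virtuals["FTML"] - virtuals["CALe"]
        x_raw = x_raw / np.linalg.norm(x_raw, axis=1, keepdims=True)
        y = np.cross(z_ref, x_raw)
        y = y / np.linalg.norm(y, axis=1, keepdims=True)
        z = np.cross(x_raw, y)
        raw = np.stack([x_raw, y, z], axis=2)

        # stance snapshot of the same construction
        up = calibration.up
        p_cal = {k: calibration.local_points[k].coords for k in ("CALe", "MT1")}
        names, ref = calibration.tech_ref["forefoot"]
        mt5_stance = ref[names.index("MT5")]
        ftml_stance = 0.5 * (p_cal["MT1"] + mt5_stance)
        x0 = ftml_stance - p_cal["CALe"]
        x0 = x0 / np.linalg.norm(x0)
        z0 = calibration.anat_local_R["hindfoot"][:, 2]
        y0 = np.cross(z0, x0)
        y0 /= np.linalg.norm(y0)
        raw0 = np.column_stack([x0, y0, np.cross(x0, y0)])
        corr = raw0.T @ calibration.anat_local_R["foot"]
        rotations["foot"] = raw @ corr
        origins["foot"] = virtuals["CALe"]
        provenance["foot"] = "per-frame CALe->FTML with hindfoot vertical, stance-corrected"

    return (
        SegmentFrameSet(origins=origins, rotations=rotations, provenance=provenance),
        VirtualPoints(points=virtuals),
    )
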