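"""Forward-kinematic generator of marker trajectories with ground truth.

A pelvis-thigh-shank chain with an articulated foot (hindfoot, midfoot,
forefoot, first metatarsal, hallux) is posed by composing prescribed joint
rotations down the chain; markers ride rigidly in their segment frames and
optional i.i.d. Gaussian noise emulates instrument error.  The generator
emits every trial type of the study protocol:

* ``natural`` — the calibration stance (all anatomical markers present),
* ``functional_turnout`` / ``forced_turnout`` — static first positions,
* ``saute`` — consecutive two-leg jumps at the controlled tempo
  (default 95 beats per minute, ten cycles), pelvis height modulated via
  a knee-flexion waveform with the foot planted,
* ``lunge`` — femoral-epicondyle calibration,
* ``squat_circumduction`` — knee-hinge squats plus hip circumduction for
  the functional joint calibration (SARA / SCoRE),
* ``seated_passive_er`` / ``seated_active_er`` — seated external
  tibiofemoral rotation.

Ground truth records the prescribed clinical joint-angle waveforms, true
virtual-marker positions, true demi-plie frames, the true navicular
height and pelvis height, so every pipeline stage can be checked for
recovery.

The default static joint offsets are the group means reported for the
four study conditions (degrees; see :mod:`footkin.reference`), so that a
default cohort reproduces the published effect sizes.  All angles are
clinical conventions: eversion, abduction and external rotation positive,
either side.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from .jointkin import compose_jcs, side_sign
from .markerio import Trial

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "default_geometry",
    "default_condition_offsets",
    "generate_trial",
    "generate_subject",
    "generate_cohort",
    "simulate_cohort_values",
]

TRIAL_LABELS = (
    "natural",
    "functional_turnout",
    "forced_turnout",
    "saute",
    "lunge",
    "squat_circumduction",
    "seated_passive_er",
    "seated_active_er",
)

# reproducible per-label noise streams
_LABEL_INDEX = {lbl: i for i, lbl in enumerate(TRIAL_LABELS)}


def default_geometry() -> dict:
    """Plausible adult right-leg geometry, mm, lab x anterior / y left /
    z up.  Declared test geometry, not an anthropometric claim.  Chosen so
    that every anatomical-frame recipe is exactly axis-aligned in the
    neutral pose (all stance angles zero) and the hallux marker lies on
    the first-metatarsal anterior axis (zero MTPJ angle at neutral)."""
    MT1 = np.array([150.0, 32.0, 28.0])
    MTB1 = np.array([78.0, 32.0, 35.0])
    HAL = MT1 + 0.6 * (MT1 - MTB1)
    return {
        "joints": {
            "hip": np.array([0.0, 0.0, 870.0]),
            "knee": np.array([0.0, -5.0, 460.0]),
            "ankle": np.array([4.0, -2.5, 90.0]),
            "midtarsal": np.array([35.0, 8.0, 45.0]),
            "tmt": np.array([75.0, 0.0, 35.0]),
            "tmt1": MTB1.copy(),
            "mtpj": MT1.copy(),
        },
        "markers": {
            "pelvis": {
                "PEL1": [-80.0, 60.0, 960.0],
                "PEL2": [-80.0, -60.0, 960.0],
                "PEL3": [60.0, 70.0, 950.0],
                "PEL4": [60.0, -70.0, 950.0],
            },
            # thigh and shank triads are rigid cluster plates of the size
            # used in instrumented gait setups (~80 mm marker spread)
            "thigh": {
                "TH1": [45.0, -65.0, 645.0],
                "TH2": [-30.0, -80.0, 610.0],
                "TH3": [15.0, -55.0, 550.0],
                "LEP": [0.0, -55.0, 460.0],
                "MEP": [0.0, 45.0, 460.0],
            },
            "tibia": {
                "TB1": [40.0, -45.0, 300.0],
                "TB2": [-30.0, -60.0, 265.0],
                "TB3": [10.0, -35.0, 215.0],
                "LMAL": [4.0, -45.0, 85.0],
                "MMAL": [4.0, 40.0, 95.0],
            },
            "hindfoot": {
                "CAL": [-55.0, 0.0, 40.0],
                "SUS": [0.0, 38.0, 35.0],
                "HDL": [-10.0, -38.0, 62.0],
                "CALe": [5.0, 0.0, 30.0],
            },
            "midfoot": {
                # NAV is anatomical only: the arch-drop degree of freedom
                # displaces it vertically, so it cannot serve in the
                # rigid tracking cluster
                "NAV": [42.0, 33.0, 48.0],
                "MFM": [40.0, 30.0, 40.0],
                "CUB": [40.0, -25.0, 30.0],
                "MFD": [60.0, 2.5, 45.0],
            },
            "forefoot": {
                "MT2": [160.0, 15.0, 30.0],
                "MT5": [150.0, -32.0, 28.0],
                "MTB2": [80.0, 15.0, 35.0],
            },
            "first_metatarsal": {
                "MTB1": MTB1.tolist(),
                "MTS1": [102.0, 30.0, 50.0],
                "MTS2": [118.0, 44.0, 32.0],
                "MT1": MT1.tolist(),
            },
            "hallux": {"HAL": HAL.tolist()},
        },
        # calibration-only markers and the trials that include them
        "calibration_markers": {
            "LMAL": ("natural",),
            "MMAL": ("natural",),
            "CALe": ("natural",),
            "MT1": ("natural",),
            "LEP": ("natural", "lunge"),
            "MEP": ("natural", "lunge"),
        },
    }


def default_condition_offsets() -> dict[str, dict[str, float]]:
    """Static clinical joint offsets per condition (degrees).

    The four study conditions use the published group means for the
    reported variables; hindfoot (ankle-complex) abduction and knee
    external rotation are set to plausible turnout contributions."""
    return {
        "natural": {
            "hindfoot_eversion": 1.1,
            "hindfoot_abduction": 5.0,
            "midfoot_abduction": 2.8,
            "forefoot_abduction": 7.6,
            "mtpj_abduction": 10.7,
            "knee_external_rotation": 5.0,
            "navicular_drop_mm": 0.0,
        },
        "functional_turnout": {
            "hindfoot_eversion": 5.7,
            "hindfoot_abduction": 12.0,
            "midfoot_abduction": 5.6,
            "forefoot_abduction": 8.4,
            "mtpj_abduction": 12.0,
            "knee_external_rotation": 12.0,
            "navicular_drop_mm": 1.6,
        },
        "forced_turnout": {
            "hindfoot_eversion": 7.1,
            "hindfoot_abduction": 15.0,
            "midfoot_abduction": 6.3,
            "forefoot_abduction": 8.8,
            "mtpj_abduction": 13.5,
            "knee_external_rotation": 15.0,
            "navicular_drop_mm": 1.9,
        },
        "saute": {  # values attained at the demi-plie instants
            "hindfoot_eversion": 15.8,
            "hindfoot_abduction": 12.0,
            "midfoot_abduction": 7.7,
            "forefoot_abduction": 8.7,
            "mtpj_abduction": 13.1,
            "knee_external_rotation": 12.0,
            "navicular_drop_mm": 12.9,
        },
        "seated_passive_er": {"knee_external_rotation": 45.0},
        "seated_active_er": {"knee_external_rotation": 38.0},
    }


@dataclass
class SynthConfig:
    """Study-condition parameters of the synthetic protocol."""

    seed: int = 0
    rate: float = 250.0
    tempo_bpm: float = 95.0
    n_cycles: int = 10
    noise_sd: float = 0.0
    #: optional soft-tissue-artifact hook: low-frequency sinusoidal marker
    #: displacement (mm amplitude, Hz), off by default
    sta_amplitude_mm: float = 0.0
    sta_freq_hz: float = 1.5
    side: str = "right"
    static_duration_s: float = 1.0
    knee_flexion_amp_deg: float = 50.0
    ankle_dorsiflexion_amp_deg: float = 15.0
    cycle_jitter: float = 0.03
    placement_deg: dict[str, float] = field(
        default_factory=lambda: {
            "natural": 10.0,
            "functional_turnout": 60.0,
            "forced_turnout": 70.0,
            "saute": 60.0,
        }
    )
    condition_offsets: dict[str, dict[str, float]] = field(
        default_factory=default_condition_offsets
    )
    geometry: dict = field(default_factory=default_geometry)


@dataclass
class GroundTruth:
    """Per-frame truth emitted alongside a synthetic trial."""

    angles: dict[str, np.ndarray]  # clinical degrees per frame
    virtual: dict[str, np.ndarray]  # true virtual-marker positions, mm
    navicular_height: np.ndarray  # true NAV vertical coordinate, mm
    pelvis_height: np.ndarray  # true pelvis-centroid vertical coordinate
    plie_frames: np.ndarray | None = None  # saute only


def _rz(deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


_JOINT_ANGLE_MAP = {
    # joint -> (sagittal key, frontal clinical key, transverse clinical key)
    "ankle": ("ankle_dorsiflexion", "hindfoot_eversion", "hindfoot_abduction"),
    "midtarsal": (None, None, "midfoot_abduction"),
    "tmt": (None, None, "forefoot_abduction"),
    "tmt1": (None, None, None),
    "mtpj": (None, None, "mtpj_abduction"),
    "knee": ("knee_flexion", None, "knee_external_rotation"),
}


def _joint_rotations(
    waveforms: dict[str, np.ndarray], n: int, side: str
) -> dict[str, np.ndarray]:
    """Compose per-frame relative rotation stacks for every joint from the
    clinical waveforms (missing waveforms are zero)."""
    s = side_sign(side)
    zeros = np.zeros(n)

    def get(key):
        if key is None:
            return zeros
        return np.broadcast_to(np.asarray(waveforms.get(key, 0.0), dtype=float), (n,))

    E = {}
    for joint, (sag, fro, tra) in _JOINT_ANGLE_MAP.items():
        R = compose_jcs(get(sag), s * get(fro), s * get(tra))
        E[joint] = R.reshape(n, 3, 3)
    return E


def _forward_model(
    config: SynthConfig,
    waveforms: dict[str, np.ndarray],
    n: int,
    root: str,
    placement_deg: float = 0.0,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """World rotation (n,3,3) and origin (n,3) per segment.

    ``root="hindfoot"`` keeps the foot planted (ankle fixed at its rest
    position, whole chain rotated by the foot-placement angle about the
    vertical); ``root="pelvis"`` fixes the pelvis instead.
    """
    g = config.geometry
    mirror = np.array([1.0, -1.0, 1.0]) if config.side == "left" else np.ones(3)
    J = {k: np.asarray(v, dtype=float) * mirror for k, v in g["joints"].items()}
    E = _joint_rotations(waveforms, n, config.side)
    s = side_sign(config.side)
    Rz = np.broadcast_to(_rz(s * placement_deg), (n, 3, 3))

    R: dict[str, np.ndarray] = {}
    O: dict[str, np.ndarray] = {}

    def mul(A, B):
        return np.einsum("fij,fjk->fik", A, B)

    def mulT(A, B):  # A @ B^T
        return np.einsum("fij,fkj->fik", A, B)

    def vec(Rs, v):
        return np.einsum("fij,j->fi", Rs, v)

    if root == "hindfoot":
        R["hindfoot"] = np.array(Rz)
        O["hindfoot"] = np.broadcast_to(J["ankle"], (n, 3)).copy()
        R["tibia"] = mulT(R["hindfoot"], E["ankle"])
        O["tibia"] = O["hindfoot"] + vec(R["tibia"], J["knee"] - J["ankle"])
        R["thigh"] = mulT(R["tibia"], E["knee"])
        O["thigh"] = O["tibia"] + vec(R["thigh"], J["hip"] - J["knee"])
        R["pelvis"] = np.array(Rz)
        O["pelvis"] = O["thigh"]
    elif root == "pelvis":
        R["pelvis"] = np.broadcast_to(np.eye(3), (n, 3, 3)).copy()
        O["pelvis"] = np.broadcast_to(J["hip"], (n, 3)).copy()
        hip_E = compose_jcs(
            np.broadcast_to(np.asarray(waveforms.get("hip_flexion", 0.0)), (n,)),
            np.broadcast_to(np.asarray(waveforms.get("hip_frontal", 0.0)), (n,)),
            np.broadcast_to(np.asarray(waveforms.get("hip_transverse", 0.0)), (n,)),
        ).reshape(n, 3, 3)
        R["thigh"] = mul(R["pelvis"], hip_E)
        O["thigh"] = O["pelvis"]
        R["tibia"] = mul(R["thigh"], E["knee"])
        O["tibia"] = O["thigh"] + vec(R["thigh"], J["knee"] - J["hip"])
        R["hindfoot"] = mul(R["tibia"], E["ankle"])
        O["hindfoot"] = O["tibia"] + vec(R["tibia"], J["ankle"] - J["knee"])
    else:
        raise ValueError(f"unknown root {root!r}")

    chain = (
        ("midfoot", "hindfoot", "midtarsal", "ankle"),
        ("forefoot", "midfoot", "tmt", "midtarsal"),
        ("first_metatarsal", "forefoot", "tmt1", "tmt"),
        ("hallux", "first_metatarsal", "mtpj", "tmt1"),
    )
    for seg, parent, joint, parent_joint in chain:
        R[seg] = mul(R[parent], E[joint])
        O[seg] = O[parent] + vec(R[parent], J[joint] - J[parent_joint])
    # segment origins above are the world positions of each segment's
    # proximal joint; markers are placed relative to those rest joints
    return R, O


_SEG_ORIGIN_JOINT = {
    "pelvis": "hip",
    "thigh": "hip",
    "tibia": "knee",
    "hindfoot": "ankle",
    "midfoot": "midtarsal",
    "forefoot": "tmt",
    "first_metatarsal": "tmt1",
    "hallux": "mtpj",
}


def _marker_world(
    config: SynthConfig, R: dict, O: dict, label: str
) -> tuple[list[str], np.ndarray]:
    g = config.geometry
    J = g["joints"]
    mirror = config.side == "left"
    names: list[str] = []
    cols: list[np.ndarray] = []
    for seg, markers in g["markers"].items():
        oj = J[_SEG_ORIGIN_JOINT[seg]]
        for name, pos in markers.items():
            only = g["calibration_markers"].get(name)
            if only is not None and label not in only:
                continue
            rest = np.asarray(pos, dtype=float)
            if mirror:
                rest = rest * np.array([1.0, -1.0, 1.0])
            oj_m = oj * np.array([1.0, -1.0, 1.0]) if mirror else oj
            names.append(name)
            cols.append(O[seg] + np.einsum("fij,j->fi", R[seg], rest - oj_m))
    return names, np.stack(cols, axis=1)


def _phase_waveform(n: int, rate: float, freq: float) -> np.ndarray:
    """0..1 modulation peaking mid-cycle: w(t) = (1 - cos(2 pi f t)) / 2."""
    t = np.arange(n) / rate
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * freq * t))


def _true_foot_abduction(
    config: SynthConfig, R: dict, O: dict, n: int
) -> np.ndarray:
    """Transverse TIB-FOOT angle computed from the true geometry, using the
    same whole-foot frame definition as the analysis (anterior axis CALe to
    FTML, hindfoot vertical as reference, neutral-pose correction)."""
    from .jointkin import jcs_angles_series

    g = config.geometry
    J = g["joints"]
    mirror = np.array([1.0, -1.0, 1.0]) if config.side == "left" else np.array([1.0, 1.0, 1.0])

    def world(seg, name):
        rest = np.asarray(g["markers"][seg][name], dtype=float) * mirror
        oj = J[_SEG_ORIGIN_JOINT[seg]] * mirror
        return O[seg] + np.einsum("fij,j->fi", R[seg], rest - oj)

    cale = world("hindfoot", "CALe")
    ftml = 0.5 * (world("first_metatarsal", "MT1") + world("forefoot", "MT5"))
    x = ftml - cale
    x = x / np.linalg.norm(x, axis=1, keepdims=True)
    z_ref = R["hindfoot"][:, :, 2]
    y = np.cross(z_ref, x)
    y = y / np.linalg.norm(y, axis=1, keepdims=True)
    raw = np.stack([x, y, np.cross(x, y)], axis=2)
    # neutral-pose snapshot of the same construction
    cale0 = np.asarray(g["markers"]["hindfoot"]["CALe"], dtype=float) * mirror
    ftml0 = 0.5 * (
        np.asarray(g["markers"]["first_metatarsal"]["MT1"], dtype=float)
        + np.asarray(g["markers"]["forefoot"]["MT5"], dtype=float)
    ) * mirror
    x0 = ftml0 - cale0
    x0 /= np.linalg.norm(x0)
    y0 = np.cross([0.0, 0.0, 1.0], x0)
    y0 /= np.linalg.norm(y0)
    raw0 = np.column_stack([x0, y0, np.cross(x0, y0)])
    foot_R = np.einsum("fij,jk->fik", raw, raw0.T)
    ang = jcs_angles_series(R["tibia"], foot_R)
    return ang[:, 2] * side_sign(config.side)


def generate_trial(config: SynthConfig, label: str) -> tuple[Trial, GroundTruth]:
    """Generate one trial of the protocol with its ground truth.

    Raises
    ------
    ValueError
        For an unknown trial label.
    """
    if label not in TRIAL_LABELS:
        raise ValueError(f"unknown trial label {label!r}")
    rng = np.random.default_rng([config.seed, _LABEL_INDEX[label]])
    rate = config.rate
    plie_frames = None

    if label in ("natural", "functional_turnout", "forced_turnout"):
        n = max(int(round(config.static_duration_s * rate)), 8)
        offsets = config.condition_offsets.get(label, {})
        waveforms = {k: np.full(n, v) for k, v in offsets.items()}
        root, placement = "hindfoot", config.placement_deg.get(label, 0.0)
    elif label == "saute":
        freq = config.tempo_bpm / 60.0
        n = int(round(config.n_cycles / freq * rate))
        w = _phase_waveform(n, rate, freq)
        base = config.condition_offsets.get("natural", {})
        peak = config.condition_offsets.get("saute", {})
        keys = set(base) | set(peak)
        waveforms = {
            k: base.get(k, 0.0) + (peak.get(k, 0.0) - base.get(k, 0.0)) * w for k in keys
        }
        # per-cycle knee-flexion amplitude jitter makes the pelvis-height
        # excursions realistically inconsistent between jumps
        t = np.arange(n) / rate
        cycle = np.minimum((t * freq).astype(int), config.n_cycles - 1)
        amp = config.knee_flexion_amp_deg * (
            1.0 + config.cycle_jitter * rng.standard_normal(config.n_cycles)
        )
        waveforms["knee_flexion"] = amp[cycle] * w
        waveforms["ankle_dorsiflexion"] = config.ankle_dorsiflexion_amp_deg * w
        plie_frames = np.round((np.arange(config.n_cycles) + 0.5) / freq * rate).astype(int)
        plie_frames = plie_frames[plie_frames < n]
        root, placement = "hindfoot", config.placement_deg.get(label, 0.0)
    elif label == "lunge":
        n = max(int(round(config.static_duration_s * rate)), 8)
        waveforms = {"knee_flexion": np.full(n, 30.0), "hip_flexion": np.full(n, 25.0)}
        root, placement = "pelvis", 0.0
    elif label == "squat_circumduction":
        n = int(round(8.0 * rate))
        t = np.arange(n) / rate
        waveforms = {
            "knee_flexion": 30.0 - 30.0 * np.cos(2.0 * np.pi * 0.5 * t),
            "hip_flexion": 20.0 + 18.0 * np.sin(2.0 * np.pi * 0.5 * t),
            "hip_frontal": 16.0 * np.cos(2.0 * np.pi * 0.5 * t),
            "hip_transverse": 10.0 * np.sin(2.0 * np.pi * 0.25 * t),
        }
        root, placement = "pelvis", 0.0
    else:  # seated external-rotation trials
        n = max(int(round(config.static_duration_s * rate)), 8)
        er = config.condition_offsets.get(label, {}).get("knee_external_rotation", 0.0)
        waveforms = {
            "hip_flexion": np.full(n, 80.0),
            "knee_flexion": np.full(n, 80.0),
            "knee_external_rotation": np.full(n, er),
        }
        root, placement = "pelvis", 0.0

    R, O = _forward_model(config, waveforms, n, root, placement)
    names, data = _marker_world(config, R, O, label)
    # arch lowering: a prescribed vertical displacement of the navicular
    # tuberosity marker (a soft-tissue deformation no rigid segment carries)
    arch_drop = np.broadcast_to(
        np.asarray(waveforms.get("navicular_drop_mm", 0.0), dtype=float), (n,)
    )
    if "NAV" in names:
        data = data.copy()
        data[:, names.index("NAV"), 2] -= arch_drop
    truth_angles = {
        k: np.broadcast_to(np.asarray(v, dtype=float), (n,)).copy()
        for k, v in waveforms.items()
    }
    truth_angles["foot_abduction"] = _true_foot_abduction(config, R, O, n)

    mirror = np.array([1.0, -1.0, 1.0]) if config.side == "left" else np.ones(3)
    g = config.geometry

    def world_point(seg, rest):
        rest = np.asarray(rest, dtype=float) * mirror
        oj = g["joints"][_SEG_ORIGIN_JOINT[seg]] * mirror
        return O[seg] + np.einsum("fij,j->fi", R[seg], rest - oj)

    mt1 = world_point("first_metatarsal", g["markers"]["first_metatarsal"]["MT1"])
    mt5 = world_point("forefoot", g["markers"]["forefoot"]["MT5"])
    mtb1 = world_point("first_metatarsal", g["markers"]["first_metatarsal"]["MTB1"])
    virtual = {
        "LMAL": world_point("tibia", g["markers"]["tibia"]["LMAL"]),
        "MMAL": world_point("tibia", g["markers"]["tibia"]["MMAL"]),
        "CALe": world_point("hindfoot", g["markers"]["hindfoot"]["CALe"]),
        "MT1": mt1,
        "KJC": 0.5
        * (
            world_point("thigh", g["markers"]["thigh"]["LEP"])
            + world_point("thigh", g["markers"]["thigh"]["MEP"])
        ),
        "FTML": 0.5 * (mt1 + mt5),
        "MidMet": 0.5 * (mtb1 + mt1),
    }
    nav = world_point("midfoot", g["markers"]["midfoot"]["NAV"])
    nav = nav - np.outer(arch_drop, [0.0, 0.0, 1.0])
    pelvis_markers = [
        world_point("pelvis", p) for p in g["markers"]["pelvis"].values()
    ]
    pelvis_height = np.mean([p[:, 2] for p in pelvis_markers], axis=0)

    if config.sta_amplitude_mm > 0:
        # low-frequency pseudo-artifact: per-marker random direction and
        # phase, sinusoidal in time (deterministic given the seed)
        tgrid = np.arange(n) / rate
        direc = rng.normal(size=(1, data.shape[1], 3))
        direc /= np.linalg.norm(direc, axis=2, keepdims=True)
        phase = rng.uniform(0, 2 * np.pi, size=(1, data.shape[1], 1))
        wave = np.sin(2 * np.pi * config.sta_freq_hz * tgrid[:, None, None] + phase)
        data = data + config.sta_amplitude_mm * wave * direc
    if config.noise_sd > 0:
        data = data + rng.normal(0.0, config.noise_sd, size=data.shape)

    trial = Trial(
        label=label,
        rate=rate,
        markers=names,
        data=data,
        lab_up_axis="z",
        side=config.side,
    )
    truth = GroundTruth(
        angles=truth_angles,
        virtual=virtual,
        navicular_height=nav[:, 2],
        pelvis_height=pelvis_height,
        plie_frames=plie_frames,
    )
    return trial, truth


def generate_subject(
    config: SynthConfig,
    labels: tuple[str, ...] = TRIAL_LABELS,
    n_static_repeats: int = 3,
) -> tuple[dict[str, list[Trial]], dict[str, GroundTruth]]:
    """All trials of one subject.  Repeated static conditions re-use the
    same prescribed offsets with independent noise; truth is recorded once
    per label."""
    trials: dict[str, list[Trial]] = {}
    truths: dict[str, GroundTruth] = {}
    for label in labels:
        reps = n_static_repeats if label in ("functional_turnout", "forced_turnout") else 1
        out = []
        for r in range(reps):
            cfg = replace(config, seed=config.seed + 101 * r)
            trial, truth = generate_trial(cfg, label)
            out.append(trial)
        trials[label] = out
        truths[label] = truth
    return trials, truths


def generate_cohort(
    template: SynthConfig,
    n_subjects: int = 18,
    effects: dict[str, dict[str, float]] | None = None,
    sd_subject: float = 3.0,
    sd_noise: float = 1.0,
    seed: int = 0,
):
    """Per-subject configurations with random offsets around the condition
    means, plus a truth table of the generative means.

    ``effects`` maps clinical angle name -> condition label -> mean
    (defaults to the study-condition offsets).  Each subject draws one
    random intercept per variable (shared across conditions, SD
    ``sd_subject``) plus independent condition noise (SD ``sd_noise``),
    giving the within-subject correlation a repeated-measures design
    needs.

    Returns ``(configs, truth)`` where ``configs`` is a list of
    :class:`SynthConfig` and ``truth`` a tidy DataFrame of the generative
    per-subject condition values.
    """
    import pandas as pd

    if n_subjects < 2:
        raise ValueError("need >= 2 subjects")
    base = default_condition_offsets()
    if effects is None:
        effects = {
            var: {c: base[c][var] for c in base if var in base[c]}
            for var in {k for d in base.values() for k in d}
        }
    rng = np.random.default_rng(seed)
    configs, rows = [], []
    for i in range(n_subjects):
        offsets = {c: dict(v) for c, v in base.items()}
        for var, cond_means in effects.items():
            u = rng.normal(0.0, sd_subject)
            for cond, mean in cond_means.items():
                val = mean + u + rng.normal(0.0, sd_noise)
                offsets.setdefault(cond, {})[var] = val
                rows.append(
                    {"subject": i, "condition": cond, "variable": var, "value": val}
                )
        configs.append(replace(template, seed=seed * 1009 + i, condition_offsets=offsets))
    return configs, pd.DataFrame(rows)


def simulate_cohort_values(
    means: dict[str, dict[str, float]],
    n_subjects: int,
    sd_subject: float = 3.0,
    sd_noise: float = 1.0,
    seed: int = 0,
):
    """Directly simulate per-subject condition values (no marker data):
    value_ij = mean_j + subject intercept_i + noise_ij.  Returns a tidy
    DataFrame with subject / condition / variable / value columns."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    rows = []
    for var, cond_means in means.items():
        conds = list(cond_means)
        u = rng.normal(0.0, sd_subject, size=n_subjects)
        e = rng.normal(0.0, sd_noise, size=(n_subjects, len(conds)))
        for i in range(n_subjects):
            for j, c in enumerate(conds):
                rows.append(
                    {
                        "subject": i,
                        "condition": c,
                        "variable": var,
                        "value": cond_means[c] + u[i] + e[i, j],
                    }
                )
    return pd.DataFrame(rows)
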