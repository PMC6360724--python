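"""Marker-trajectory I/O and marker-set schema validation.

The canonical on-disk format is a TRC-like tab-separated text file:

    rate_hz <tab> 250.0
    units   <tab> mm
    up_axis <tab> z
    label   <tab> saute
    side    <tab> right
    frame <tab> time <tab> CAL_X <tab> CAL_Y <tab> CAL_Z <tab> ...
    0 <tab> 0.000 <tab> -45.0 <tab> ...

Coordinates are millimetres internally; files declaring ``units: m`` are
converted on read.  Gaps (occluded markers) are encoded as the sentinel
``NA`` and carried as an explicit boolean mask — the pipeline refuses to
interpolate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np

__all__ = [
    "Trial",
    "MarkerSchema",
    "ValidationReport",
    "DEFAULT_SCHEMA",
    "read_trial",
    "write_trial",
    "validate_trial",
    "FormatError",
    "SchemaError",
]

CONDITIONS = (
    "natural",
    "functional_turnout",
    "forced_turnout",
    "saute",
    "lunge",
    "squat_circumduction",
    "seated_passive_er",
    "seated_active_er",
)

_GAP_SENTINEL = "NA"


class FormatError(ValueError):
    """Raised when a trajectory file is malformed."""


class SchemaError(ValueError):
    """Raised when marker names conflict with the marker-set schema."""


@dataclass
class Trial:
    """A labelled block of 3D marker trajectories.

    Parameters
    ----------
    label : str
        Condition tag, one of :data:`CONDITIONS`.
    rate : float
        Sampling rate in Hz (must be positive).
    markers : list of str
        Ordered marker names; ``data[:, i]`` belongs to ``markers[i]``.
    data : ndarray, shape (n_frames, n_markers, 3)
        Coordinates in millimetres.
    lab_up_axis : {"x", "y", "z"}
        Which laboratory axis is vertical.
    gaps : ndarray of bool, shape (n_frames, n_markers), optional
        True where a marker sample is missing.  Coordinates under a gap
        flag are undefined (stored as NaN).
    side : {"right", "left"}
        Which limb the marker set is on.
    """

    label: str
    rate: float
    markers: list[str]
    data: np.ndarray
    lab_up_axis: str = "z"
    gaps: np.ndarray | None = None
    side: str = "right"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[2] != 3:
            raise ValueError(f"data must be (frames, markers, 3), got {self.data.shape}")
        if self.data.shape[1] != len(self.markers):
            raise ValueError("marker count mismatch between names and data")
        if len(set(self.markers)) != len(self.markers):
            raise SchemaError("duplicate marker names")
        if not self.rate > 0:
            raise ValueError("rate must be positive")
        if self.lab_up_axis not in ("x", "y", "z"):
            raise ValueError("lab_up_axis must be one of x, y, z")
        if self.gaps is None:
            self.gaps = np.zeros(self.data.shape[:2], dtype=bool)
        else:
            self.gaps = np.asarray(self.gaps, dtype=bool)
            if self.gaps.shape != self.data.shape[:2]:
                raise ValueError("gaps mask shape mismatch")
        # finite everywhere except under an explicit gap flag
        bad = ~np.isfinite(self.data).all(axis=2) & ~self.gaps
        if bad.any():
            raise ValueError("non-finite coordinates outside flagged gaps")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def up_index(self) -> int:
        return "xyz".index(self.lab_up_axis)

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.rate

    def get(self, name: str) -> np.ndarray:
        """Trajectory of one marker, shape (n_frames, 3)."""
        try:
            i = self.markers.index(name)
        except ValueError:
            raise KeyError(f"marker {name!r} not in trial") from None
        return self.data[:, i]

    def has(self, name: str) -> bool:
        return name in self.markers

    def gap_fraction(self, name: str) -> float:
        i = self.markers.index(name)
        return float(self.gaps[:, i].mean())


@dataclass
class MarkerSchema:
    """Which markers belong to which segment, and which points are virtual.

    ``segments`` maps a segment name to ``(anatomical, technical)`` marker
    name lists; technical markers form the tracked cluster.  Each virtual
    marker is owned by exactly one segment (the segment whose technical
    frame it is reconstructed in).
    """

    segments: dict[str, tuple[list[str], list[str]]]
    virtual_markers: dict[str, str]
    side: str = "right"

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for seg, (anat, tech) in self.segments.items():
            for m in list(anat) + list(tech):
                if m in seen and seen[m] != seg:
                    raise SchemaError(f"marker {m!r} appears in {seen[m]} and {seg}")
                seen[m] = seg
        for vm, owner in self.virtual_markers.items():
            if owner not in self.segments:
                raise SchemaError(f"virtual marker {vm!r} owned by unknown segment {owner!r}")

    def technical(self, segment: str) -> list[str]:
        return list(self.segments[segment][1])

    def anatomical(self, segment: str) -> list[str]:
        return list(self.segments[segment][0])

    def all_markers(self) -> list[str]:
        names: list[str] = []
        for anat, tech in self.segments.values():
            for m in anat + tech:
                if m not in names:
                    names.append(m)
        return names

    def required_tracking(self) -> list[str]:
        names: list[str] = []
        for _, tech in self.segments.values():
            for m in tech:
                if m not in names:
                    names.append(m)
        return names


def _default_schema() -> MarkerSchema:
    # (anatomical, technical) per segment; technical = tracked cluster.
    segments = {
        "pelvis": ([], ["PEL1", "PEL2", "PEL3", "PEL4"]),
        "thigh": (["LEP", "MEP"], ["TH1", "TH2", "TH3"]),
        "tibia": (["LMAL", "MMAL"], ["TB1", "TB2", "TB3"]),
        "hindfoot": (["CAL", "SUS", "HDL", "CALe"], ["CAL", "SUS", "HDL"]),
        "midfoot": (["NAV"], ["MFM", "CUB", "MFD"]),
        "forefoot": (["MT5"], ["MT2", "MT5", "MTB2"]),
        "first_metatarsal": (["MTB1", "MT1", "MTS1", "MTS2"], ["MTB1", "MTS1", "MTS2"]),
        "hallux": (["HAL"], ["HAL"]),
    }
    virtual = {
        "LMAL": "tibia",
        "MMAL": "tibia",
        "CALe": "hindfoot",
        "MT1": "first_metatarsal",
        "MidMet": "first_metatarsal",
        "X_MET": "first_metatarsal",
        "FTML": "forefoot",
        "KJC": "thigh",
    }
    return MarkerSchema(segments=segments, virtual_markers=virtual)


DEFAULT_SCHEMA = _default_schema()


@dataclass
class ValidationReport:
    passed: bool
    missing: dict[str, list[str]] = field(default_factory=dict)
    gap_fractions: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)


def validate_trial(
    trial: Trial, schema: MarkerSchema, gap_threshold: float = 0.05
) -> ValidationReport:
    """Check a trial against a marker schema (report-only, never raises).

    Passes iff every technical marker of every segment is present and no
    present marker exceeds ``gap_threshold`` gap fraction.  Markers with
    gaps below the threshold produce warnings.
    """
    missing: dict[str, list[str]] = {}
    for seg, (_anat, tech) in schema.segments.items():
        lost = [m for m in tech if not trial.has(m)]
        if lost:
            missing[seg] = lost
    gap_fr = {m: trial.gap_fraction(m) for m in trial.markers}
    warnings = []
    ok = not missing
    for m, f in gap_fr.items():
        if f > gap_threshold:
            ok = False
            warnings.append(f"marker {m}: gap fraction {f:.3f} exceeds {gap_threshold}")
        elif f > 0:
            warnings.append(f"marker {m}: gap fraction {f:.3f}")
    return ValidationReport(passed=ok, missing=missing, gap_fractions=gap_fr, warnings=warnings)


def write_trial(trial: Trial, path) -> str:
    """Write a trial to the TRC-like TSV format.  Returns the path."""
    lines = [
        f"rate_hz\t{trial.rate!r}",
        "units\tmm",
        f"up_axis\t{trial.lab_up_axis}",
        f"label\t{trial.label}",
        f"side\t{trial.side}",
    ]
    head = ["frame", "time"]
    for m in trial.markers:
        head += [f"{m}_X", f"{m}_Y", f"{m}_Z"]
    lines.append("\t".join(head))
    times = trial.times()
    for i in range(trial.n_frames):
        row = [str(i), f"{times[i]:.9f}"]
        for j in range(len(trial.markers)):
            if trial.gaps[i, j]:
                row += [_GAP_SENTINEL] * 3
            else:
                row += [f"{v:.9f}" for v in trial.data[i, j]]
        lines.append("\t".join(row))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return str(path)


def read_trial(path, format: str = "tsv") -> Trial:
    """Read a trial from disk.

    ``format="tsv"`` reads the canonical TRC-like format.  ``format="c3d"``
    delegates to :mod:`ezc3d` when available.
    """
    if format == "c3d":
        return _read_c3d(path)
    if format != "tsv":
        raise FormatError(f"unknown format {format!r}")

    with open(path) as fh:
        raw = [ln.rstrip("\n") for ln in fh if ln.strip()]
    header: dict[str, str] = {}
    i = 0
    while i < len(raw) and "\t" in raw[i]:
        key, _, val = raw[i].partition("\t")
        if key == "frame":
            break
        header[key] = val.strip()
        i += 1
    for req in ("rate_hz", "units", "up_axis", "label"):
        if req not in header:
            raise FormatError(f"missing header field {req!r}")
    if i >= len(raw):
        raise FormatError("missing column header row")
    cols = raw[i].split("\t")
    if cols[:2] != ["frame", "time"] or (len(cols) - 2) % 3 != 0:
        raise FormatError("malformed column header")
    markers = []
    for c in cols[2::3]:
        if not c.endswith("_X"):
            raise FormatError(f"expected *_X column, got {c!r}")
        markers.append(c[:-2])
    if len(set(markers)) != len(markers):
        raise SchemaError("duplicate marker names in header")

    n_m = len(markers)
    rows = raw[i + 1 :]
    data = np.full((len(rows), n_m, 3), np.nan)
    gaps = np.zeros((len(rows), n_m), dtype=bool)
    for r, line in enumerate(rows):
        fields = line.split("\t")
        if len(fields) != 2 + 3 * n_m:
            raise FormatError(f"row {r}: expected {2 + 3 * n_m} fields, got {len(fields)}")
        for j in range(n_m):
            trip = fields[2 + 3 * j : 5 + 3 * j]
            if _GAP_SENTINEL in trip:
                gaps[r, j] = True
            else:
                data[r, j] = [float(v) for v in trip]
    scale = {"mm": 1.0, "m": 1000.0}.get(header["units"])
    if scale is None:
        raise FormatError(f"unknown units {header['units']!r}")
    data = data * scale
    return Trial(
        label=header["label"],
        rate=float(header["rate_hz"]),
        markers=markers,
        data=data,
        lab_up_axis=header["up_axis"],
        gaps=gaps,
        side=header.get("side", "right"),
    )


def _read_c3d(path) -> Trial:  # pragma: no cover - optional dependency
    try:
        import ezc3d
    except ImportError as exc:
        raise FormatError("c3d support requires the ezc3d package") from exc
    c3d = ezc3d.c3d(str(path))
    labels = [s.strip() for s in c3d["parameters"]["POINT"]["LABELS"]["value"]]
    rate = float(c3d["parameters"]["POINT"]["RATE"]["value"][0])
    pts = c3d["data"]["points"]  # 4 x markers x frames
    data = np.transpose(pts[:3], (2, 1, 0))
    gaps = ~np.isfinite(data).all(axis=2)
    data[gaps] = np.nan
    return Trial(label="natural", rate=rate, markers=labels, data=data, gaps=gaps)
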