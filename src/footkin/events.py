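"""Demi-plié event detection and per-event extraction for saute trials.

Kinematic values are read out at the instant of deepest knee bend in each
jump cycle, operationalised as a local minimum of the pelvis vertical
height (pelvis cluster centroid).  Three consecutive cycles with the most
consistent pelvis-height excursions are selected and each variable is
averaged over those three demi-plie frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "EventSet",
    "EventError",
    "detect_minima",
    "cycle_excursions",
    "select_consistent_triplet",
    "extract_at_events",
    "default_min_cycle_s",
]


class EventError(ValueError):
    """Too few events for the requested extraction."""


@dataclass
class EventSet:
    """Detected demi-plie instants of one saute trial."""

    minima_frames: np.ndarray  # frame index per cycle, strictly increasing
    excursions: np.ndarray  # peak-to-trough pelvis height per cycle, mm
    selected: tuple[int, int, int]  # consecutive cycle indices chosen

    @property
    def selected_frames(self) -> np.ndarray:
        return self.minima_frames[list(self.selected)]


def default_min_cycle_s(tempo_bpm: float = 95.0) -> float:
    """Minimum separation between demi-plies: 0.4 beat periods."""
    return 0.4 * 60.0 / tempo_bpm


def detect_minima(
    pelvis_height: np.ndarray,
    rate: float,
    min_cycle_s: float | None = None,
    min_prominence_frac: float = 0.1,
) -> np.ndarray:
    """Local minima of the pelvis height separated by at least
    ``min_cycle_s`` seconds; plateau ties resolve to the earliest frame.

    Minima shallower than ``min_prominence_frac`` of the signal's
    peak-to-peak range are ignored: residual noise ripple on the nearly
    flat tops between jumps would otherwise register as extra cycles.

    Raises
    ------
    EventError
        If no local minimum exists (e.g. a flat signal).
    """
    x = np.asarray(pelvis_height, dtype=float)
    if min_cycle_s is None:
        min_cycle_s = default_min_cycle_s()
    if min_cycle_s <= 0:
        raise ValueError("min_cycle_s must be positive")
    distance = max(int(round(min_cycle_s * rate)), 1)
    prominence = min_prominence_frac * float(np.ptp(x)) if np.ptp(x) > 0 else None
    idx, props = find_peaks(-x, distance=distance, plateau_size=1, prominence=prominence)
    # find_peaks reports plateau midpoints; take the left edge for ties
    if idx.size and "left_edges" in props:
        idx = props["left_edges"]
    if idx.size < 1:
        raise EventError("no pelvis-height minima found")
    return idx.astype(int)


def cycle_excursions(pelvis_height: np.ndarray, minima: np.ndarray) -> np.ndarray:
    """Peak-to-trough excursion per cycle: the highest pelvis height in the
    window between the neighbouring minima, minus the height at the
    minimum."""
    x = np.asarray(pelvis_height, dtype=float)
    minima = np.asarray(minima, dtype=int)
    bounds = np.concatenate([[0], (minima[1:] + minima[:-1]) // 2, [len(x) - 1]])
    exc = np.empty(len(minima))
    for k, m in enumerate(minima):
        window = x[bounds[k] : bounds[k + 1] + 1]
        exc[k] = window.max() - x[m]
    return exc


def select_consistent_triplet(
    minima: np.ndarray, excursions: np.ndarray
) -> tuple[int, int, int]:
    """The consecutive triplet of cycles minimising the coefficient of
    variation of excursion; ties break to the earliest triplet.

    Raises
    ------
    EventError
        With fewer than 3 cycles.
    """
    minima = np.asarray(minima)
    exc = np.asarray(excursions, dtype=float)
    if len(minima) != len(exc):
        raise ValueError("minima and excursions differ in length")
    if len(minima) < 3:
        raise EventError(f"need >= 3 cycles, got {len(minima)}")
    best, best_cv = 0, np.inf
    for k in range(len(minima) - 2):
        window = exc[k : k + 3]
        mean = window.mean()
        cv = np.inf if mean == 0 else window.std() / mean
        if cv < best_cv - 1e-15:
            best, best_cv = k, cv
    return (best, best + 1, best + 2)


def extract_at_events(
    series: dict[str, np.ndarray], events: EventSet
) -> dict[str, float]:
    """Mean over the three selected demi-plie frames, per variable.

    Raises
    ------
    IndexError
        If a selected frame lies outside a series.
    """
    frames = events.selected_frames
    out = {}
    for name, values in series.items():
        v = np.asarray(values, dtype=float)
        if frames.max() >= len(v):
            raise IndexError(f"event frame {frames.max()} outside series {name!r}")
        out[name] = float(v[frames].mean())
    return out
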