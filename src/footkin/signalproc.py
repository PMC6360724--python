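"""Zero-lag low-pass filtering and residual analysis for cutoff selection.

Marker trajectories from jump trials are smoothed with a zero-phase
Butterworth filter (forward and backward passes, so the net order is twice
the per-pass order and no phase lag is introduced).  The cutoff frequency
is either supplied (the pipeline default is 26 Hz) or chosen by Winter's
residual analysis: the RMS residual between the raw and filtered signal is
evaluated over a grid of cutoffs, a straight line is fitted to the
high-frequency tail of that curve (where the residual is dominated by
noise), and the chosen cutoff is the lowest frequency whose residual does
not exceed the line's intercept at 0 Hz — the noise-amplitude estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt

__all__ = ["ResidualCurve", "lowpass_zero_lag", "residual_analysis", "DEFAULT_CUTOFF_HZ"]

#: Pipeline default cutoff for jump-trial marker data (Hz).
DEFAULT_CUTOFF_HZ = 26.0


@dataclass
class ResidualCurve:
    """Residual-vs-cutoff curve with the Winter-style cutoff choice.

    Attributes
    ----------
    cutoffs : ndarray
        Evaluated cutoff grid, Hz.
    residuals : ndarray
        RMS(raw - filtered) at each cutoff, same units as the signal (mm).
    chosen_cutoff : float
        Smallest grid cutoff whose residual is at or below the noise
        intercept.
    noise_intercept : float
        Intercept at 0 Hz of the straight line fitted to the tail of the
        residual curve; estimates the RMS noise amplitude.
    """

    cutoffs: np.ndarray
    residuals: np.ndarray
    chosen_cutoff: float
    noise_intercept: float


def lowpass_zero_lag(
    signal: np.ndarray, rate: float, cutoff: float, order: int = 4
) -> np.ndarray:
    """Zero-phase low-pass Butterworth filter of a 1-D (or columns of a 2-D) series.

    ``order`` is the net order; each of the forward/backward passes uses a
    Butterworth design of ``order/2``.  No cutoff-frequency correction is
    applied for the dual pass.  Edges are handled by odd reflection padding
    of ``3 * order`` samples.

    Raises
    ------
    ValueError
        If the cutoff is not inside (0, Nyquist), the order is not a
        positive even integer, or the signal is shorter than
        ``3 * order + 1`` samples.
    """
    x = np.asarray(signal, dtype=float)
    nyq = rate / 2.0
    if not 0 < cutoff < nyq:
        raise ValueError(f"cutoff {cutoff} Hz outside (0, {nyq}) Hz")
    if order < 2 or order % 2:
        raise ValueError("order must be a positive even integer")
    padlen = 3 * order
    if x.shape[0] <= padlen:
        raise ValueError(f"signal length {x.shape[0]} too short for order {order}")
    b, a = butter(order // 2, cutoff / nyq, btype="low")
    return filtfilt(b, a, x, axis=0, padtype="odd", padlen=padlen)


def residual_analysis(
    signal: np.ndarray,
    rate: float,
    grid: np.ndarray | None = None,
    order: int = 4,
    tail_fraction: float = 0.5,
    rel_floor: float = 0.02,
) -> ResidualCurve:
    """Winter-style residual analysis for automatic cutoff selection.

    Parameters
    ----------
    signal : 1-D array
        Raw series (one marker coordinate, mm).
    rate : float
        Sampling rate, Hz.
    grid : array, optional
        Candidate cutoffs; default 1..50 Hz in 1 Hz steps (clipped below
        Nyquist).
    tail_fraction : float
        Upper fraction of the grid treated as the noise-dominated linear
        tail for the straight-line fit.
    rel_floor : float
        Acceptance floor as a fraction of the centred signal's RMS.  A
        noise-free signal has a ~zero intercept that its power-law
        residual decay never crosses; the floor regularises that limit.
        The chosen cutoff is the smallest grid frequency whose residual is
        at or below ``max(intercept, rel_floor * rms(signal - mean))``.

    Raises
    ------
    ValueError
        If the grid leaves fewer than 3 tail points for the line fit.
    """
    x = np.asarray(signal, dtype=float)
    if grid is None:
        grid = np.arange(1.0, 51.0)
    grid = np.asarray(grid, dtype=float)
    nyq = rate / 2.0
    grid = grid[(grid > 0) & (grid < nyq)]
    resid = np.empty(grid.shape)
    for i, fc in enumerate(grid):
        resid[i] = np.sqrt(np.mean((x - lowpass_zero_lag(x, rate, fc, order)) ** 2))
    n_tail = max(int(np.ceil(len(grid) * tail_fraction)), 0)
    if n_tail < 3:
        raise ValueError("residual analysis needs at least 3 tail points for the line fit")
    fx, fy = grid[-n_tail:], resid[-n_tail:]
    slope, intercept = np.polyfit(fx, fy, 1)
    intercept = max(intercept, 0.0)
    threshold = max(intercept, rel_floor * float(np.sqrt(np.mean((x - x.mean()) ** 2))))
    below = np.nonzero(resid <= threshold + 1e-12)[0]
    chosen = grid[below[0]] if below.size else grid[-1]
    return ResidualCurve(
        cutoffs=grid,
        residuals=resid,
        chosen_cutoff=float(chosen),
        noise_intercept=float(intercept),
    )
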