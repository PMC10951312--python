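"""Cardiac-pulse synchronisation: peak detection and phase binning.

Each B-scan frame is phase-wrapped to the cardiac cycle: its timestamp is
located between the two nearest systolic peaks of the pulse trace and mapped
to a phase in [0, 1) (linear interpolation between peaks; a peak defines
phase 0). The cycle is divided into ``n_bins`` equal intervals (100 by
default) and the frame assigned to ``floor(phase * n_bins)``. Frames before
the first or after the last detected peak belong to no complete cycle and are
left unassigned (phase NaN, bin -1).
"""

from __future__ import annotations

import numpy as np
from scipy.signal import find_peaks

from .errors import ConfigError, InsufficientCyclesError
from .types import BinAssignment, PulseTrace

__all__ = ["detect_peaks", "assign_bins", "DEFAULT_MIN_PERIOD_S"]

#: Refractory period between detected peaks; ~180 bpm ceiling.
DEFAULT_MIN_PERIOD_S = 0.33


def detect_peaks(
    trace: PulseTrace,
    min_period_s: float = DEFAULT_MIN_PERIOD_S,
    prominence_frac: float = 0.25,
) -> PulseTrace:
    """Detect systolic peaks and return a copy of the trace carrying them.

    Peaks are local maxima separated by at least ``min_period_s`` with
    prominence above ``prominence_frac`` times the trace's amplitude range.

    Raises
    ------
    InsufficientCyclesError
        If fewer than two peaks are found (no complete cycle exists).
    """
    if min_period_s <= 0:
        raise ConfigError("min_period_s must be strictly positive")
    if trace.sample_times.size == 0:
        raise InsufficientCyclesError("empty pulse trace")
    amp_range = float(np.ptp(trace.intensities))
    dt = trace.sampling_interval_s
    distance = max(1, int(round(min_period_s / dt)))
    if amp_range == 0:
        raise InsufficientCyclesError("constant pulse trace: no peaks")
    idx, _ = find_peaks(
        trace.intensities, distance=distance, prominence=prominence_frac * amp_range
    )
    if idx.size < 2:
        raise InsufficientCyclesError(
            f"found {idx.size} pulse peak(s); need at least 2 for one complete cycle"
        )
    return trace.with_peaks(trace.sample_times[idx])


def assign_bins(
    frame_times: np.ndarray, trace: PulseTrace, n_bins: int = 100
) -> BinAssignment:
    """Assign each frame timestamp to a cardiac-phase bin.

    For a frame at time ``t`` with consecutive peaks ``t_k <= t < t_{k+1}``,
    ``phase = (t - t_k) / (t_{k+1} - t_k)`` and
    ``bin = floor(phase * n_bins)`` clamped to ``n_bins - 1``.
    """
    if n_bins < 1:
        raise ConfigError("n_bins must be >= 1")
    if trace.peak_times is None or trace.peak_times.size < 2:
        raise InsufficientCyclesError("trace has fewer than 2 peaks; run detect_peaks first")
    frame_times = np.asarray(frame_times, dtype=float)
    if frame_times.size > 1 and np.any(np.diff(frame_times) < 0):
        raise ConfigError("frame_times must be sorted")

    peaks = trace.peak_times
    idx = np.searchsorted(peaks, frame_times, side="right")
    phase = np.full(frame_times.shape, np.nan)
    bins = np.full(frame_times.shape, -1, dtype=int)
    inside = (idx >= 1) & (idx < peaks.size)
    k = idx[inside] - 1
    ph = (frame_times[inside] - peaks[k]) / (peaks[k + 1] - peaks[k])
    phase[inside] = ph
    bins[inside] = np.minimum((ph * n_bins).astype(int), n_bins - 1)
    return BinAssignment(n_bins=n_bins, phase=phase, bin_index=bins)
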