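"""Segment a respiration trace into cycles and map times to phase angles.

A thermistor near the nose produces a quasi-periodic voltage whose peak is
taken as phase 0 (equivalent to 2*pi) and whose trough is phase pi.  Within
each half cycle (peak->trough and trough->next peak) phase is linearly
scaled to time, so inhalation and exhalation halves of unequal duration
are each mapped onto half a turn.  Phase assignment here is exact linear
interpolation; a 1 ms lookup-table export is available for parity with
table-based pipelines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks

__all__ = [
    "RespirationTrace",
    "PhaseMap",
    "InsufficientCyclesError",
    "detect_extrema",
    "assign_phase",
    "cycle_statistics",
]

TWO_PI = 2.0 * np.pi


class InsufficientCyclesError(ValueError):
    """Raised when fewer than two full respiratory cycles are detected."""


@dataclass
class RespirationTrace:
    """A sampled respiration (thermistor-like) signal.

    samples : amplitude in arbitrary units
    sample_rate : Hz
    """

    samples: np.ndarray
    sample_rate: float

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("trace contains non-finite samples")

    @property
    def duration(self) -> float:
        """Trace duration in seconds."""
        return self.samples.size / self.sample_rate

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(self.samples.size) * (1000.0 / self.sample_rate)


@dataclass
class PhaseMap:
    """Alternating peak/trough times (ms) defining the phase mapping.

    Invariants: ``peaks`` and ``troughs`` strictly alternate, starting
    and ending on a peak, with every trough strictly inside its flanking
    peaks.  ``n_cycles = len(peaks) - 1``.
    """

    peaks: np.ndarray      # ms, ascending, length n_cycles + 1
    troughs: np.ndarray    # ms, ascending, length n_cycles

    def __post_init__(self):
        self.peaks = np.asarray(self.peaks, dtype=float)
        self.troughs = np.asarray(self.troughs, dtype=float)
        if self.peaks.size < 2 or self.troughs.size != self.peaks.size - 1:
            raise InsufficientCyclesError(
                "insufficient cycles: need >= 2 peaks with one trough between each")
        if np.any(np.diff(self.peaks) <= 0):
            raise ValueError("peaks must be strictly increasing")
        if not (np.all(self.troughs > self.peaks[:-1])
                and np.all(self.troughs < self.peaks[1:])):
            raise ValueError("each trough must lie strictly between its flanking peaks")

    @property
    def n_cycles(self) -> int:
        return self.peaks.size - 1

    @property
    def cycle_periods(self) -> np.ndarray:
        """Peak-to-peak intervals (ms)."""
        return np.diff(self.peaks)

    @property
    def anchors(self):
        """Interleaved (time, unwrapped phase) anchor points."""
        t = np.empty(self.peaks.size + self.troughs.size)
        t[0::2] = self.peaks
        t[1::2] = self.troughs
        phase = np.arange(t.size) * np.pi  # peak 0, trough pi, next peak 2pi, ...
        return t, phase

    def to_frame(self) -> pd.DataFrame:
        """Tidy (peak_time, trough_time, period) table, one row per cycle."""
        return pd.DataFrame({
            "peak_time": self.peaks[:-1],
            "trough_time": self.troughs,
            "period": self.cycle_periods,
        })

    def phase_table(self, resolution: float = 1.0):
        """Sampled (time, angle) lookup table at the given resolution (ms).

        Provided for parity with tabulated 1 ms pipelines; the primary
        :func:`assign_phase` path interpolates exactly instead.
        """
        if resolution > 1.0:
            raise ValueError("resolution must be <= 1 ms")
        t = np.arange(self.peaks[0], self.peaks[-1] + resolution / 2, resolution)
        return t, assign_phase(t, self)


def detect_extrema(trace: RespirationTrace, min_period: float = 250.0,
                   smooth_window: float = 25.0) -> PhaseMap:
    """Detect alternating peaks and troughs of a respiration trace.

    The trace is smoothed with a moving average of ``smooth_window`` ms,
    then local maxima/minima separated by at least ``min_period`` ms are
    located.  Extrema are pruned to a strictly alternating
    peak/trough/peak sequence (keeping the more extreme candidate when
    two of the same polarity are adjacent) and trimmed to start and end
    on a peak.

    Raises :class:`InsufficientCyclesError` when fewer than two cycles
    survive (e.g. a flat trace).
    """
    if min_period <= 0:
        raise ValueError("min_period must be positive")
    dt_ms = 1000.0 / trace.sample_rate
    x = trace.samples
    win = max(int(round(smooth_window / dt_ms)), 1)
    if win > 1:
        x = uniform_filter1d(x, size=win, mode="nearest")
    span = float(np.max(x) - np.min(x))
    if span <= 0:
        raise InsufficientCyclesError("insufficient cycles: flat trace")
    dist = max(int(round(min_period / dt_ms)), 1)
    prom = 0.1 * span
    pk_idx, _ = find_peaks(x, distance=dist, prominence=prom)
    tr_idx, _ = find_peaks(-x, distance=dist, prominence=prom)
    events = sorted([(i, +1) for i in pk_idx] + [(i, -1) for i in tr_idx])
    if not events:
        raise InsufficientCyclesError("insufficient cycles: no extrema found")
    # enforce alternation: among runs of equal polarity keep the extreme one
    pruned = []
    for idx, pol in events:
        if pruned and pruned[-1][1] == pol:
            prev_idx, _ = pruned[-1]
            better = (x[idx] > x[prev_idx]) if pol > 0 else (x[idx] < x[prev_idx])
            if better:
                pruned[-1] = (idx, pol)
        else:
            pruned.append((idx, pol))
    # trim to start and end on a peak
    while pruned and pruned[0][1] < 0:
        pruned.pop(0)
    while pruned and pruned[-1][1] < 0:
        pruned.pop()
    peaks = np.array([i for i, p in pruned if p > 0], dtype=float) * dt_ms
    troughs = np.array([i for i, p in pruned if p < 0], dtype=float) * dt_ms
    if peaks.size < 2:
        raise InsufficientCyclesError("insufficient cycles")
    if troughs.size != peaks.size - 1:
        raise RuntimeError("internal error: non-alternating extrema after pruning")
    return PhaseMap(peaks, troughs)


def assign_phase(times, pmap: PhaseMap, outside: str = "drop"):
    """Map times (ms) to respiratory phase angles in ``[0, 2*pi)``.

    Each half cycle is linearly and independently scaled: a peak maps to
    0, the following trough to pi, the next peak to 2*pi (== 0).  Times
    outside ``[first peak, last peak]`` are handled per ``outside``:
    ``"drop"`` removes them (with a warning via the return mask),
    ``"nan"`` yields NaN, ``"error"`` raises.

    Returns the angle array; with ``outside="drop"`` the returned array
    may be shorter than the input.
    """
    t = np.atleast_1d(np.asarray(times, dtype=float))
    anchors_t, anchors_ph = pmap.anchors
    inside = (t >= anchors_t[0]) & (t <= anchors_t[-1])
    if not np.all(inside):
        if outside == "error":
            raise ValueError("time outside mapped respiration range")
        if outside == "drop":
            t = t[inside]
        elif outside != "nan":
            raise ValueError(f"unknown outside policy {outside!r}")
    unwrapped = np.interp(t, anchors_t, anchors_ph)
    ang = unwrapped % TWO_PI
    # snap float round-off at the landmarks so peaks are exactly 0, troughs pi
    ang = np.where(np.isclose(ang, np.pi, rtol=0.0, atol=1e-9), np.pi, ang)
    ang = np.where(np.isclose(ang, TWO_PI, rtol=0.0, atol=1e-9)
                   | np.isclose(ang, 0.0, rtol=0.0, atol=1e-9), 0.0, ang)
    if outside == "nan":
        ang = np.where(inside, ang, np.nan)
    return ang


def cycle_statistics(pmap: PhaseMap) -> dict:
    """Mean/SD of peak-to-peak periods (ms) and breathing rate (Hz)."""
    periods = pmap.cycle_periods
    if periods.size < 1:
        raise InsufficientCyclesError("insufficient cycles")
    mean = float(periods.mean())
    sd = float(periods.std(ddof=1)) if periods.size > 1 else 0.0
    return {"mean_period": mean, "sd_period": sd, "rate": 1000.0 / mean,
            "n_cycles": int(periods.size)}
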