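"""Diagnostic synthetic data with known ground truth.

Every stage of the analysis chain (phase mapping, baseline subtraction,
heatmaps, circular statistics) is validated against artificial recordings
whose statistical structure is known exactly: a quasi-periodic
respiration trace, spike trains phase-locked to the cycle through a
periodic Gaussian rate bump at a chosen angle, and full pseudo-random
block-stimulation sessions with planted excitatory and suppressive sites.

Spike trains are produced by thinning an inhomogeneous Poisson process
whose rate is defined in the *phase* domain, so irregular cycle periods
automatically warp the rate bump in time exactly as the phase-based
analysis assumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .circular_stats import TWO_PI, signed_angle_diff, wrap_angle
from .receptive_field_mapping import STIM_COLUMNS, Session
from .respiration_phase import PhaseMap, RespirationTrace, assign_phase

__all__ = [
    "PhaseLockSpec",
    "PlantedSite",
    "PlantedResponseSpec",
    "synth_respiration",
    "synth_phase_locked_spikes",
    "synth_session",
]


@dataclass
class PhaseLockSpec:
    """Periodic Gaussian phase-locking of a Poisson spike train.

    The rate is ``baseline_rate`` plus a Gaussian bump of height
    ``peak_rate - baseline_rate`` and SD ``width`` radians centred (each
    cycle) at ``center_angle``.
    """

    center_angle: float = 0.0
    width: float = 0.5           # radians (circular SD of the bump)
    baseline_rate: float = 2.0   # Hz
    peak_rate: float = 40.0      # Hz

    def __post_init__(self):
        if not (self.peak_rate >= self.baseline_rate >= 0):
            raise ValueError("need peak_rate >= baseline_rate >= 0")
        if self.width <= 0:
            raise ValueError("width must be positive")

    def rate_at(self, angles):
        """Phase-domain firing rate (Hz) at the given angles."""
        d = signed_angle_diff(angles, self.center_angle)
        bump = np.exp(-0.5 * (d / self.width) ** 2)
        return self.baseline_rate + (self.peak_rate - self.baseline_rate) * bump


@dataclass
class PlantedSite:
    """A ground-truth responsive site on the field.

    For excitatory sites ``gain`` is the expected number of extra evoked
    spikes for a fully overlapping stimulus whose onset phase falls in
    ``phase_interval`` (lo, hi; circular).  For suppressive sites
    ``suppression`` in [0, 1] multiplicatively thins baseline spikes
    during the stimulus; by default they respond at every phase.
    """

    x: float
    y: float
    gain: float = 0.0
    suppression: float = 0.0
    phase_interval: tuple = (0.0, TWO_PI)
    diameter: float = 100.0      # um, glomerulus-scale

    def responsive_at(self, phase):
        lo, hi = wrap_angle(self.phase_interval[0]), wrap_angle(self.phase_interval[1])
        ph = wrap_angle(phase)
        if np.isclose(lo, hi):
            return True
        if lo < hi:
            return lo <= ph < hi
        return ph >= lo or ph < hi

    def overlap_fraction(self, x, y, side):
        """Fractional overlap of a block footprint with the site's square."""
        half = (side + self.diameter) / 2.0
        ox = max(0.0, half - abs(x - self.x)) if abs(x - self.x) < half else 0.0
        oy = max(0.0, half - abs(y - self.y)) if abs(y - self.y) < half else 0.0
        ox = min(ox, side, self.diameter)
        oy = min(oy, side, self.diameter)
        return (ox * oy) / (side * side)


@dataclass
class PlantedResponseSpec:
    excitatory_sites: list = field(default_factory=list)
    inhibitory_sites: list = field(default_factory=list)
    latency: float = 10.0        # ms from stimulus onset to evoked spikes
    response_spread: float = 60.0  # ms over which evoked spikes are spread


def synth_respiration(mean_period: float = 671.0, sd_period: float = 121.0,
                      duration: float = 120.0, seed=None,
                      sample_rate: float = 1000.0, trough_fraction: float = 0.5):
    """Quasi-sinusoidal respiration trace with known cycle landmarks.

    Per-cycle periods are drawn from a normal truncated to +-2.5 SD
    (mean must exceed twice the SD so periods stay positive); the trace
    is the cosine of the generative phase, so the exact peak/trough
    times are returned as the ground-truth :class:`PhaseMap`.

    Returns (RespirationTrace, PhaseMap).
    """
    if not mean_period > 2 * sd_period >= 0:
        raise ValueError("need mean_period > 2*sd_period >= 0")
    rng = np.random.default_rng(seed)
    total_ms = duration * 1000.0
    periods = []
    t = 0.0
    while t < total_ms + mean_period:
        if sd_period > 0:
            p = truncnorm.rvs(-2.5, 2.5, loc=mean_period, scale=sd_period,
                              random_state=rng)
        else:
            p = mean_period
        periods.append(p)
        t += p
    peaks = np.concatenate([[0.0], np.cumsum(periods)])
    troughs = peaks[:-1] + trough_fraction * np.asarray(periods)
    pmap = PhaseMap(peaks, troughs)
    times = np.arange(0.0, total_ms, 1000.0 / sample_rate)
    times = times[times <= peaks[-1]]
    angles = assign_phase(times, pmap)
    trace = RespirationTrace(np.cos(angles), sample_rate)
    return trace, pmap


def synth_phase_locked_spikes(spec: PhaseLockSpec, pmap: PhaseMap,
                              seed=None, t_range=None) -> np.ndarray:
    """Inhomogeneous Poisson spike train locked to the respiratory cycle.

    The phase-domain rate of ``spec`` is realised in time by thinning a
    homogeneous candidate process at the peak rate: each candidate time
    is mapped to its phase through ``pmap`` and kept with probability
    ``rate(phase)/peak``.  Byte-identical under a fixed seed.
    """
    rng = np.random.default_rng(seed)
    t0 = pmap.peaks[0] if t_range is None else t_range[0]
    t1 = pmap.peaks[-1] if t_range is None else t_range[1]
    lam_max = spec.peak_rate / 1000.0  # per ms
    if lam_max <= 0:
        return np.empty(0)
    n_cand = rng.poisson(lam_max * (t1 - t0))
    cand = np.sort(rng.uniform(t0, t1, n_cand))
    angles = assign_phase(cand, pmap)
    keep = rng.uniform(size=cand.size) < spec.rate_at(angles) / spec.peak_rate
    return cand[keep]


def _place_blocks(rng, n, field_size, side, min_spacing):
    """Pseudo-random non-repeating block centres over the field.

    Centres are uniform over the field minus a half-block margin, with an
    optional minimum centre-to-centre distance between *consecutive*
    stimuli (spreading out successive stimulations).  Exact repeats are
    rejected.
    """
    w, h = field_size
    lo = side / 2.0
    xs = np.empty(n)
    ys = np.empty(n)
    px = py = None
    for i in range(n):
        for attempt in range(200):
            x = rng.uniform(lo, w - lo)
            y = rng.uniform(lo, h - lo)
            if px is not None and min_spacing > 0:
                if np.hypot(x - px, y - py) < min_spacing and attempt < 199:
                    continue
            break
        xs[i], ys[i] = x, y
        px, py = x, y
    return xs, ys


def synth_session(n_stimuli: int = 600, field_size=(1000.0, 1000.0),
                  side: float = 100.0, durations=(100.0, 200.0),
                  isi: float = 200.0, planted: PlantedResponseSpec = None,
                  baseline: PhaseLockSpec = None, seed=None,
                  mean_period: float = 671.0, sd_period: float = 121.0,
                  pixel: float = 4.0, min_spacing: float = 0.0,
                  warmup: float = 1000.0):
    """Generate a full block-stimulation session with known ground truth.

    Stimuli of 100/200 ms duration separated by a 200 ms inter-stimulus
    interval are placed pseudo-randomly (no repeats) over the field.
    Spikes are the baseline phase-locked process, plus ``gain *
    overlap`` Poisson evoked spikes at the planted latency when a
    stimulus hits an excitatory site during its responsive phase
    interval, and thinned by ``suppression * overlap`` during stimuli
    over suppressive sites.

    Returns (Session, ground_truth dict).
    """
    if n_stimuli < 1:
        raise ValueError("n_stimuli must be >= 1")
    rng = np.random.default_rng(seed)
    planted = planted or PlantedResponseSpec()
    baseline = baseline or PhaseLockSpec()
    durs = rng.choice(np.asarray(durations, dtype=float), size=n_stimuli)
    onsets = warmup + np.concatenate([[0.0], np.cumsum(durs[:-1] + isi)])
    total_s = (onsets[-1] + durs[-1] + isi + warmup) / 1000.0
    trace, pmap = synth_respiration(mean_period, sd_period, total_s + 2.0,
                                    seed=rng.integers(2**31), sample_rate=1000.0)
    xs, ys = _place_blocks(rng, n_stimuli, field_size, side, min_spacing)
    phases = assign_phase(onsets, pmap, outside="nan")
    stim = pd.DataFrame({"x": xs, "y": ys, "side": side, "onset": onsets,
                         "duration": durs, "onset_phase": phases},
                        columns=STIM_COLUMNS)

    spikes = synth_phase_locked_spikes(baseline, pmap,
                                       seed=rng.integers(2**31))
    # suppression during stimuli over inhibitory sites
    if planted.inhibitory_sites:
        keep = np.ones(spikes.size, dtype=bool)
        for row in stim.itertuples():
            in_win = (spikes >= row.onset) & (spikes < row.onset + row.duration)
            if not in_win.any():
                continue
            factor = 1.0
            for site in planted.inhibitory_sites:
                ov = site.overlap_fraction(row.x, row.y, row.side)
                if ov > 0 and site.responsive_at(row.onset_phase):
                    factor *= (1.0 - site.suppression * ov)
            if factor < 1.0:
                keep[in_win] &= rng.uniform(size=int(in_win.sum())) < factor
        spikes = spikes[keep]
    # evoked spikes from excitatory sites
    evoked = []
    truth_rows = []
    for row in stim.itertuples():
        for si, site in enumerate(planted.excitatory_sites):
            ov = site.overlap_fraction(row.x, row.y, row.side)
            if ov <= 0 or not site.responsive_at(row.onset_phase):
                continue
            n_ev = rng.poisson(site.gain * ov)
            if n_ev:
                spread = min(planted.response_spread,
                             row.duration - planted.latency)
                ts = row.onset + planted.latency + rng.uniform(
                    0.0, max(spread, 1.0), n_ev)
                evoked.append(ts)
            truth_rows.append({"stim_index": row.Index, "site": si,
                               "overlap": ov, "n_evoked": int(n_ev)})
    if evoked:
        spikes = np.sort(np.concatenate([spikes] + evoked))
    session = Session(spikes, stim, pmap, field_size, pixel)
    truth = {
        "phase_map": pmap,
        "baseline": baseline,
        "planted": planted,
        "trace": trace,
        "evoked_log": pd.DataFrame(
            truth_rows, columns=["stim_index", "site", "overlap", "n_evoked"]),
    }
    return session, truth
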