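"""Phase-conditioned optogenetic receptive-field mapping.

Single 100x100 um blocks of light are flashed one at a time at
pseudo-random positions on the dorsal bulb surface while a single
mitral/tufted unit is recorded.  Because baseline firing is itself locked
to the respiratory cycle, the evoked response of each stimulus is
compared against control (stimulus-free) activity measured *at the same
respiratory phase*: the phase-binned control mean plus ``k`` standard
deviations is subtracted from the response rate before the stimulus
deposits its value onto the map.  Overlapping deposits are averaged per
pixel, smoothed with a normalized Gaussian restricted to covered pixels,
and thresholded into excitatory or inhibitory regions of interest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .circular_stats import TWO_PI, wrap_angle
from .respiration_phase import PhaseMap, assign_phase

__all__ = [
    "BlockStimulus",
    "Session",
    "BaselineProfile",
    "Heatmap",
    "ROI",
    "response_window",
    "control_window",
    "phase_conditioned_baseline",
    "build_heatmap",
    "extract_roi",
    "stimuli_hitting_roi",
    "peristimulus_histogram",
]

STIM_COLUMNS = ["x", "y", "side", "onset", "duration", "onset_phase"]


@dataclass
class BlockStimulus:
    """A single square light block: center (um), side (um), onset/duration (ms)."""

    x: float
    y: float
    onset: float
    duration: float
    side: float = 100.0
    onset_phase: float = np.nan

    def __post_init__(self):
        if self.side <= 0 or self.duration <= 0:
            raise ValueError("side and duration must be positive")


@dataclass
class Session:
    """One recording: spikes + stimulus log + respiration phase map.

    stimuli : DataFrame with columns x, y, side, onset, duration,
        onset_phase (um / ms / radians), sorted by onset.
    field_size : (width, height) of the stimulated surface in um.
    pixel : heatmap pixel size in um (4 um matches a 4x projected DMD
        pixel; 25 pixels then span one 100 um block side).
    """

    spikes: np.ndarray
    stimuli: pd.DataFrame
    phase_map: PhaseMap
    field_size: tuple = (1000.0, 1000.0)
    pixel: float = 4.0

    def __post_init__(self):
        self.spikes = np.sort(np.asarray(self.spikes, dtype=float))
        missing = [c for c in STIM_COLUMNS if c not in self.stimuli.columns]
        if missing:
            raise ValueError(f"stimuli table missing columns {missing}")
        self.stimuli = self.stimuli.sort_values("onset").reset_index(drop=True)
        if self.stimuli["onset_phase"].isna().any():
            self.stimuli["onset_phase"] = assign_phase(
                self.stimuli["onset"].to_numpy(), self.phase_map, outside="nan")

    def spike_count(self, t0: float, t1: float) -> int:
        return int(np.searchsorted(self.spikes, t1) - np.searchsorted(self.spikes, t0))

    @property
    def grid_shape(self):
        w, h = self.field_size
        return (int(round(h / self.pixel)), int(round(w / self.pixel)))


@dataclass
class BaselineProfile:
    """Phase-binned control firing statistics (mean and SD per bin, Hz)."""

    edges: np.ndarray
    mean_rate: np.ndarray
    sd_rate: np.ndarray
    n_windows: np.ndarray

    @property
    def n_bins(self) -> int:
        return self.mean_rate.size

    def bin_of(self, angle):
        idx = (wrap_angle(angle) / TWO_PI * self.n_bins).astype(int)
        return np.minimum(idx, self.n_bins - 1)

    def threshold_at(self, angle, k: float):
        """Control mean + k*SD at the bin containing ``angle``."""
        b = self.bin_of(np.atleast_1d(angle))
        return self.mean_rate[b] + k * self.sd_rate[b]


@dataclass
class Heatmap:
    """Spatial evoked-response field: value grid + per-pixel stimulus coverage.

    Pixels never covered by any stimulus footprint are NaN (undefined),
    never zero.  ``grid`` rows index y, columns x.
    """

    grid: np.ndarray
    coverage: np.ndarray
    sigma: float
    pixel: float
    units: str = "hz"

    @property
    def covered(self) -> np.ndarray:
        return self.coverage > 0

    def to_frame(self) -> pd.DataFrame:
        ny, nx = self.grid.shape
        yy, xx = np.mgrid[0:ny, 0:nx]
        return pd.DataFrame({"x_um": (xx.ravel() + 0.5) * self.pixel,
                             "y_um": (yy.ravel() + 0.5) * self.pixel,
                             "value": self.grid.ravel(),
                             "coverage": self.coverage.ravel()})


@dataclass
class ROI:
    """Connected region of interest on a heatmap."""

    mask: np.ndarray
    polarity: str                # "excitatory" | "inhibitory"
    threshold_used: float
    peak_value: float            # max value (excitatory) or min value (inhibitory)
    centroid_um: tuple = (np.nan, np.nan)

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


def response_window(stim, margin: float = 50.0):
    """Evoked-response window: stimulus onset to ``margin`` ms before light-off."""
    if margin < 0:
        raise ValueError("margin must be >= 0")
    end = stim.onset + stim.duration - margin
    if end <= stim.onset:
        raise ValueError("response window of non-positive length "
                         f"(duration {stim.duration} <= margin {margin})")
    return (stim.onset, end)


def control_window(stim, prev_offset: float, gap: float = 50.0):
    """Stimulus-free window preceding ``stim``.

    Starts ``gap`` ms after the previous light-off and ends at the
    current onset.  Returns None (skipped) when no positive-length
    stimulus-free interval exists.
    """
    start = prev_offset + gap
    if start >= stim.onset:
        return None
    return (start, stim.onset)


def _iter_stimuli(session: Session):
    for row in session.stimuli.itertuples(index=True):
        yield row


def _control_windows(session: Session, gap: float = 50.0,
                     margin: float = 50.0):
    """(t0, t1, phase-at-start) control window per stimulus, where possible.

    Each stimulus's control window is truncated to the length of its own
    response window (taking the last part of the stimulus-free interval,
    ending at onset), so control and response rates are exchangeable
    under the null and the control SD calibrates the subtraction.  The
    first stimulus uses the pre-session baseline segment by convention.
    """
    out = []
    prev_off = float(session.phase_map.peaks[0])
    for row in _iter_stimuli(session):
        stim = BlockStimulus(row.x, row.y, row.onset, row.duration, row.side)
        if row.Index == 0:
            win = (prev_off, row.onset) if row.onset > prev_off else None
        else:
            win = control_window(stim, prev_off, gap)
        if win is not None:
            resp_len = row.duration - margin
            if resp_len > 0:
                t0 = max(win[0], win[1] - resp_len)
                ph = assign_phase([t0], session.phase_map, outside="nan")[0]
                if np.isfinite(ph) and win[1] > t0:
                    out.append((t0, win[1], ph, row.Index))
        prev_off = row.onset + row.duration
    return out


def phase_conditioned_baseline(session: Session, n_bins: int = 12,
                               gap: float = 50.0) -> BaselineProfile:
    """Mean and SD of control-window firing rate per respiratory phase bin.

    Each inter-stimulus control window is assigned to the bin of its
    start phase (windows span a range of angles; the start-phase binning
    matches how stimulations are grouped by their start times).  Bins
    with no control window are flagged with a warning and get NaN.
    """
    if len(session.stimuli) == 0:
        raise ValueError("empty session")
    wins = _control_windows(session, gap)
    if not wins:
        raise ValueError("no usable control windows")
    edges = np.linspace(0.0, TWO_PI, n_bins + 1)
    rates = [[] for _ in range(n_bins)]
    for t0, t1, ph, _ in wins:
        b = min(int(ph / TWO_PI * n_bins), n_bins - 1)
        rates[b].append(session.spike_count(t0, t1) / ((t1 - t0) / 1000.0))
    mean = np.full(n_bins, np.nan)
    sd = np.full(n_bins, np.nan)
    n = np.zeros(n_bins, dtype=int)
    for b, vals in enumerate(rates):
        n[b] = len(vals)
        if vals:
            v = np.asarray(vals)
            mean[b] = v.mean()
            sd[b] = v.std(ddof=1) if v.size > 1 else 0.0
    if np.any(n == 0):
        warnings.warn(f"{int((n == 0).sum())} phase bins have no control window")
    return BaselineProfile(edges, mean, sd, n)


def _footprint_slices(session: Session, x, y, side):
    """Pixel slice of an axis-aligned block footprint, clipped to the field."""
    px = session.pixel
    ny, nx = session.grid_shape
    i0 = max(int(np.floor((y - side / 2) / px)), 0)
    i1 = min(int(np.ceil((y + side / 2) / px)), ny)
    j0 = max(int(np.floor((x - side / 2) / px)), 0)
    j1 = min(int(np.ceil((x + side / 2) / px)), nx)
    return slice(i0, i1), slice(j0, j1)


def _in_phase_range(phases, phase_range):
    lo, hi = wrap_angle(phase_range[0]), wrap_angle(phase_range[1])
    ph = wrap_angle(phases)
    if lo <= hi:
        return (ph >= lo) & (ph < hi)
    return (ph >= lo) | (ph < hi)   # interval wraps through 0


def smooth_covered(grid, covered, sigma: float):
    """Gaussian smoothing normalized over covered pixels only.

    Uncovered pixels contribute neither mass nor normalisation, so ROI
    edges are not dragged toward unexplored space.  ``sigma = 0`` is the
    identity.
    """
    out = np.where(covered, grid, np.nan)
    if sigma <= 0:
        return out
    num = ndimage.gaussian_filter(np.where(covered, grid, 0.0), sigma)
    den = ndimage.gaussian_filter(covered.astype(float), sigma)
    with np.errstate(invalid="ignore", divide="ignore"):
        sm = num / den
    return np.where(covered, sm, np.nan)


def build_heatmap(session: Session, baseline: BaselineProfile = None,
                  k: float = 1.5, sigma: float = 4.0, phase_range=None,
                  margin: float = 50.0, units: str = "hz") -> Heatmap:
    """Deposit baseline-subtracted evoked responses onto the field grid.

    Every contributing stimulus deposits ``response - (control mean +
    k*SD)`` (both at its onset-phase bin) uniformly over its footprint;
    pixels hit by several blocks average their deposits; the result is
    Gaussian-smoothed with ``sigma`` (pixel units) over covered pixels.
    With ``baseline=None`` no subtraction is applied (the raw-activity
    map used for inhibitory "dark region" detection).

    units: "hz" for rates over the response window, "counts" for raw
    spike counts above the expected control count.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    ny, nx = session.grid_shape
    acc = np.zeros((ny, nx))
    cov = np.zeros((ny, nx), dtype=int)
    stim = session.stimuli
    sel = np.ones(len(stim), dtype=bool)
    if phase_range is not None:
        sel &= _in_phase_range(stim["onset_phase"].to_numpy(), phase_range)
    sel &= stim["duration"].to_numpy() > margin
    if not sel.any():
        raise ValueError("empty selection: no stimuli in phase_range")
    for row in stim[sel].itertuples():
        t0, t1 = row.onset, row.onset + row.duration - margin
        dur_s = (t1 - t0) / 1000.0
        count = session.spike_count(t0, t1)
        if units == "hz":
            value = count / dur_s
        else:
            value = float(count)
        if baseline is not None:
            thr = float(baseline.threshold_at(row.onset_phase, k)[0])
            if not np.isfinite(thr):
                continue   # bin with no control data: skip deposit
            value -= thr * (1.0 if units == "hz" else dur_s)
        si, sj = _footprint_slices(session, row.x, row.y, row.side)
        acc[si, sj] += value
        cov[si, sj] += 1
    covered = cov > 0
    with np.errstate(invalid="ignore"):
        mean_grid = np.where(covered, acc / np.maximum(cov, 1), 0.0)
    grid = smooth_covered(mean_grid, covered, sigma)
    return Heatmap(grid, cov, sigma, session.pixel, units)


def extract_roi(hmap: Heatmap, polarity: str = "excitatory",
                threshold: float = 0.0, min_pixels: int = 120,
                min_coverage: int = 5):
    """Connected threshold-crossing regions, strongest first.

    Excitatory: covered pixels with value > threshold (on a
    baseline-subtracted map).  Inhibitory: covered pixels with value <
    threshold on an *unsubtracted* map — the dark regions where
    stimulation suppressed activity below the control level (8 Hz
    default in group analyses; a 5 Hz variant is also in use).
    Returns [] when nothing crosses.

    ``min_coverage`` excludes pixels hit by fewer than that many
    stimulus blocks: the mapping strategy relies on overlapping blocks
    sampling each region many times, and a pixel averaged over only one
    or two deposits cannot support a significance claim.  The default
    ``min_pixels`` of 120 is the area of the smallest glomerulus (50 um
    diameter) at 4 um pixels; smaller components are speckle.
    """
    if not hmap.covered.any():
        raise ValueError("heatmap has no covered pixels")
    vals = hmap.grid
    sampled = hmap.coverage >= min_coverage
    if polarity == "excitatory":
        mask = sampled & (vals > threshold)
    elif polarity == "inhibitory":
        mask = sampled & (vals < threshold)
    else:
        raise ValueError(f"unknown polarity {polarity!r}")
    mask &= np.isfinite(vals)
    labels, n = ndimage.label(mask)
    rois = []
    for lab in range(1, n + 1):
        m = labels == lab
        if m.sum() < min_pixels:
            continue
        v = vals[m]
        peak = float(v.max()) if polarity == "excitatory" else float(v.min())
        cy, cx = ndimage.center_of_mass(m)
        rois.append(ROI(m, polarity, threshold, peak,
                        ((cx + 0.5) * hmap.pixel, (cy + 0.5) * hmap.pixel)))
    rois.sort(key=lambda r: r.peak_value, reverse=(polarity == "excitatory"))
    return rois


def stimuli_hitting_roi(session: Session, roi: ROI) -> pd.DataFrame:
    """Stimuli whose footprint intersects the ROI, with overlap fraction."""
    if roi.n_pixels == 0:
        raise ValueError("empty ROI")
    px = session.pixel
    rows = []
    for row in _iter_stimuli(session):
        si, sj = _footprint_slices(session, row.x, row.y, row.side)
        patch = roi.mask[si, sj]
        if patch.size == 0:
            continue
        # geometric overlap: each mask pixel contributes its area clipped
        # to the (continuous) block rectangle
        ii = np.arange(si.start, si.stop)
        jj = np.arange(sj.start, sj.stop)
        oy = (np.minimum((ii + 1) * px, row.y + row.side / 2)
              - np.maximum(ii * px, row.y - row.side / 2)).clip(min=0.0)
        ox = (np.minimum((jj + 1) * px, row.x + row.side / 2)
              - np.maximum(jj * px, row.x - row.side / 2)).clip(min=0.0)
        area = (oy[:, None] * ox[None, :] * patch).sum()
        frac = float(area) / (row.side * row.side)
        if frac > 0:
            rows.append({**{c: getattr(row, c) for c in STIM_COLUMNS},
                         "overlap_fraction": frac, "index": row.Index})
    return pd.DataFrame(rows, columns=STIM_COLUMNS + ["overlap_fraction", "index"])


def peristimulus_histogram(session: Session, stimuli: pd.DataFrame = None,
                           bin_ms: float = 25.0, t_max: float = None,
                           gap: float = 50.0) -> dict:
    """Trial-averaged PSTH aligned to stimulus onset, with paired control.

    For every selected stimulus, spike counts in ``bin_ms`` bins from
    onset to ``t_max`` (default: the shortest stimulus duration) are
    converted to rates; the mean +- SE across trials is returned.  The
    control PSTH aligns the same horizon to the start of each trial's
    phase-matched (preceding) control window, counting only time that
    actually falls inside the window (exposure-corrected).
    """
    if bin_ms <= 0:
        raise ValueError("bin must be positive")
    stim = session.stimuli if stimuli is None else stimuli
    if len(stim) == 0:
        raise ValueError("empty stimulus subset")
    if t_max is None:
        t_max = float(stim["duration"].min())
    edges = np.arange(0.0, t_max + bin_ms / 2, bin_ms)
    nb = edges.size - 1
    sel_idx = set(stim["index"]) if "index" in stim.columns else set(stim.index)
    trial_rates = []
    ctrl_counts = np.zeros(nb)
    ctrl_expo = np.zeros(nb)
    ctrl_lookup = {i: (t0, t1) for t0, t1, _, i in _control_windows(session, gap)}
    for row in stim.itertuples():
        onset = row.onset
        rel = session.spikes[(session.spikes >= onset) &
                             (session.spikes < onset + t_max)] - onset
        counts = np.histogram(rel, bins=edges)[0]
        trial_rates.append(counts / (bin_ms / 1000.0))
        key = getattr(row, "index", row.Index) if "index" in stim.columns else row.Index
        if key in ctrl_lookup:
            c0, c1 = ctrl_lookup[key]
            horizon = min(t_max, c1 - c0)
            relc = session.spikes[(session.spikes >= c0) &
                                  (session.spikes < c0 + horizon)] - c0
            ctrl_counts += np.histogram(relc, bins=edges)[0]
            expo = np.clip(horizon - edges[:-1], 0, bin_ms)
            ctrl_expo += expo / 1000.0
    trial_rates = np.asarray(trial_rates)
    n = trial_rates.shape[0]
    mean = trial_rates.mean(axis=0)
    se = trial_rates.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(nb)
    with np.errstate(invalid="ignore", divide="ignore"):
        ctrl_rate = np.where(ctrl_expo > 0, ctrl_counts / ctrl_expo, np.nan)
    return {"edges": edges, "rate": mean, "se": se, "n_trials": n,
            "control_rate": ctrl_rate}
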