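"""Circular (directional) statistics for respiratory-phase-resolved firing.

Spike or stimulus-onset angles on the respiratory cycle are summarised as
phase-binned polar profiles, their vector-mean centroids, and two classical
directional tests: Rayleigh's test for non-uniformity and Fisher's
nonparametric multi-sample test for a common circular median (the circular
analogue of a Kruskal-Wallis test).  Group-level utilities rotate each
unit's profiles so the control centroid sits at angle 0 and scale to
control peak 1, so profiles from heterogeneous units can be averaged.

Conventions
-----------
Angles are radians in ``[0, 2*pi)`` with 0 = respiration-trace peak
(transition from inhalation to exhalation) and ``pi`` = trough.  Signed
angular differences are wrapped to ``(-pi, pi]``; a negative centroid
shift means activity moved to an *earlier* phase of the cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _sps

__all__ = [
    "PolarProfile",
    "CentroidStats",
    "wrap_angle",
    "signed_angle_diff",
    "bin_polar",
    "bin_polar_trials",
    "centroid",
    "circular_median",
    "rayleigh_test",
    "equal_medians_test",
    "rotate_profile",
    "rotate_and_scale",
    "compare_conditions",
    "group_ttests",
]

TWO_PI = 2.0 * np.pi


def wrap_angle(theta):
    """Wrap angle(s) to ``[0, 2*pi)``."""
    return np.asarray(theta, dtype=float) % TWO_PI


def signed_angle_diff(a, b):
    """Signed circular difference ``a - b`` wrapped to ``(-pi, pi]``."""
    d = (np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % TWO_PI
    return np.where(d > np.pi, d - TWO_PI, d)


@dataclass
class PolarProfile:
    """Phase-binned firing-rate profile over one respiratory cycle.

    ``rate`` is in Hz when an exposure (seconds spent per bin) was supplied
    at construction, otherwise it is a raw weighted count per bin.
    """

    edges: np.ndarray          # n_bins + 1 monotone edges tiling [0, 2pi]
    rate: np.ndarray           # Hz (or counts) per bin
    se: np.ndarray             # standard error per bin, same units as rate
    n_obs: np.ndarray          # observations contributing per bin

    def __post_init__(self):
        self.edges = np.asarray(self.edges, dtype=float)
        self.rate = np.asarray(self.rate, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        self.n_obs = np.asarray(self.n_obs)
        if self.edges.size != self.rate.size + 1:
            raise ValueError("edges must have n_bins + 1 entries")
        if np.any(self.rate < 0):
            raise ValueError("rates must be non-negative")

    @property
    def n_bins(self) -> int:
        return self.rate.size

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.edges)

    def scaled(self, factor: float) -> "PolarProfile":
        return PolarProfile(self.edges.copy(), self.rate * factor,
                            self.se * factor, self.n_obs.copy())


@dataclass
class CentroidStats:
    """Vector-mean summary of phase-distributed activity.

    angle : preferred phase (radians, [0, 2pi)); meaningless if not
        ``defined`` (zero resultant).
    magnitude : mean resultant length in [0, 1] (dimensionless).
    polar_area : area enclosed by the piecewise-constant polar curve,
        ``0.5 * sum(r_i^2 * dtheta_i)`` (Hz^2 for rate profiles).
    """

    angle: float
    magnitude: float
    polar_area: float = np.nan
    peak_rate: float = np.nan
    mean_rate: float = np.nan
    defined: bool = True


def _bin_edges(n_bins: int) -> np.ndarray:
    return np.linspace(0.0, TWO_PI, n_bins + 1)


def bin_polar(angles, weights=None, n_bins: int = 12, exposure=None) -> PolarProfile:
    """Bin angles into ``n_bins`` equal sectors of the cycle.

    Parameters
    ----------
    angles : array-like
        Event angles (radians, any real values; wrapped internally).
    weights : array-like, optional
        Per-event weights (e.g. spike counts per stimulation).
    n_bins : int
        Number of equal-width sectors tiling ``[0, 2*pi)``.
    exposure : float or array-like, optional
        Seconds of observation per bin (scalar = same for every bin).
        When given, rates are per-second (Hz) with Poisson standard
        errors; otherwise raw weighted counts are returned.
    """
    angles = wrap_angle(np.atleast_1d(angles))
    if angles.size == 0:
        raise ValueError("bin_polar requires at least one angle")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    edges = _bin_edges(n_bins)
    w = np.ones_like(angles) if weights is None else np.asarray(weights, dtype=float)
    idx = np.minimum((angles / TWO_PI * n_bins).astype(int), n_bins - 1)
    counts = np.bincount(idx, weights=w, minlength=n_bins)
    n_obs = np.bincount(idx, minlength=n_bins)
    if exposure is None:
        rate = counts
        se = np.sqrt(np.maximum(counts, 0.0))
    else:
        expo = np.broadcast_to(np.asarray(exposure, dtype=float), (n_bins,))
        if np.any(expo <= 0):
            raise ValueError("exposure must be positive")
        rate = counts / expo
        se = np.sqrt(np.maximum(counts, 0.0)) / expo
    return PolarProfile(edges, rate, se, n_obs)


def bin_polar_trials(trial_angles, n_bins: int = 12, trial_exposure=None) -> PolarProfile:
    """Per-trial binned rates averaged across trials (SE across trials).

    ``trial_angles`` is a sequence of angle arrays (one per trial/cycle);
    ``trial_exposure`` the seconds each trial spends per bin (scalar,
    per-bin array, or per-trial-per-bin array).  This is the estimator
    used for simulated runs, where every cycle is one trial.
    """
    trial_angles = list(trial_angles)
    n_trials = len(trial_angles)
    if n_trials == 0:
        raise ValueError("no trials")
    edges = _bin_edges(n_bins)
    per_trial = np.zeros((n_trials, n_bins))
    for i, ang in enumerate(trial_angles):
        ang = wrap_angle(np.atleast_1d(np.asarray(ang, dtype=float)))
        if ang.size:
            idx = np.minimum((ang / TWO_PI * n_bins).astype(int), n_bins - 1)
            per_trial[i] = np.bincount(idx, minlength=n_bins)
    if trial_exposure is not None:
        expo = np.broadcast_to(np.asarray(trial_exposure, dtype=float),
                               per_trial.shape)
        per_trial = per_trial / expo
    rate = per_trial.mean(axis=0)
    se = (per_trial.std(axis=0, ddof=1) / np.sqrt(n_trials)
          if n_trials > 1 else np.zeros(n_bins))
    n_obs = np.full(n_bins, n_trials)
    return PolarProfile(edges, rate, se, n_obs)


def _resultant(angles, weights):
    w = np.ones_like(angles) if weights is None else np.asarray(weights, dtype=float)
    total = w.sum()
    if total <= 0:
        raise ValueError("total weight must be positive")
    c = float(np.sum(w * np.cos(angles))) / total
    s = float(np.sum(w * np.sin(angles))) / total
    return c, s, total


def centroid(x, weights=None, atol: float = 1e-12) -> CentroidStats:
    """Centroid (vector mean) of raw angles or of a :class:`PolarProfile`.

    For a profile the "data points" are the bin centres weighted by bin
    rate, and the rate-derived summaries (polar area, peak and mean rate)
    are filled in; for raw angles those fields are NaN.  A zero resultant
    (perfectly balanced data) yields ``magnitude 0`` with the angle
    flagged undefined rather than an arbitrary direction.
    """
    if isinstance(x, PolarProfile):
        ang = x.centers
        w = x.rate if weights is None else np.asarray(weights, dtype=float)
        polar_area = 0.5 * float(np.sum(x.rate**2 * x.widths))
        peak = float(np.max(x.rate))
        mean = float(np.mean(x.rate))
    else:
        ang = wrap_angle(np.atleast_1d(x))
        if ang.size == 0:
            raise ValueError("centroid of empty sample")
        w = weights
        polar_area = peak = mean = np.nan
    w_arr = np.ones_like(ang) if w is None else np.asarray(w, dtype=float)
    if w_arr.sum() <= 0:
        return CentroidStats(np.nan, 0.0, polar_area, peak, mean, defined=False)
    c, s, _ = _resultant(ang, w)
    r = float(np.hypot(c, s))
    if r <= atol:
        return CentroidStats(np.nan, 0.0, polar_area, peak, mean, defined=False)
    return CentroidStats(float(np.arctan2(s, c)) % TWO_PI, r,
                         polar_area, peak, mean, defined=True)


def rayleigh_test(angles, weights=None) -> dict:
    """Rayleigh test for non-uniformity of circular data.

    Returns ``{"z": n*Rbar^2, "p": ...}`` using the standard
    small-sample-corrected approximation
    ``p = exp(sqrt(1 + 4n + 4(n^2 - R^2)) - (1 + 2n))`` with ``R = n*Rbar``
    (the contract of the CircStat toolbox ``circ_rtest``).
    """
    ang = wrap_angle(np.atleast_1d(angles))
    n = ang.size
    if n < 4:
        raise ValueError("Rayleigh test needs n >= 4")
    c, s, total = _resultant(ang, weights)
    rbar = float(np.hypot(c, s))
    if weights is None:
        n_eff = float(n)
    else:
        n_eff = float(total)
    big_r = n_eff * rbar
    z = big_r**2 / n_eff
    p = float(np.exp(np.sqrt(1.0 + 4.0 * n_eff + 4.0 * (n_eff**2 - big_r**2))
                     - (1.0 + 2.0 * n_eff)))
    return {"z": float(z), "p": min(max(p, 0.0), 1.0), "rbar": rbar, "n": n_eff}


def circular_median(angles) -> float:
    """Circular median: the direction minimising mean circular distance.

    Evaluated over data points and their antipodes (the minimiser of the
    sum of arc distances always lies at one of these for finite samples).
    """
    ang = wrap_angle(np.atleast_1d(angles))
    if ang.size == 0:
        raise ValueError("median of empty sample")
    candidates = np.concatenate([ang, wrap_angle(ang + np.pi)])
    # mean arc distance from each candidate to every data point
    d = np.abs(signed_angle_diff(ang[None, :], candidates[:, None]))
    cost = d.mean(axis=1)
    best = np.flatnonzero(np.isclose(cost, cost.min(), atol=1e-12))
    # tie-break toward the centroid direction for stability
    cen = centroid(ang)
    if cen.defined and best.size > 1:
        off = np.abs(signed_angle_diff(candidates[best], cen.angle))
        return float(candidates[best[np.argmin(off)]])
    return float(candidates[best[0]])


def _common_median_statistic(groups, med):
    """Fisher's chi-square statistic for equal circular medians."""
    n = np.array([g.size for g in groups], dtype=float)
    m = np.array([float(np.sum(signed_angle_diff(g, med) < 0)) for g in groups])
    N = n.sum()
    M = m.sum()
    if M <= 0 or M >= N:
        raise ValueError(
            "pooled circular median degenerate (all points on one side); "
            "equal-medians test undefined for this sample")
    P = (N**2 / (M * (N - M))) * float(np.sum(m**2 / n)) - N * M / (N - M)
    return float(P)


def equal_medians_test(groups, method: str = "chi2",
                       n_permutations: int = 2000, seed=None) -> dict:
    """Multi-sample nonparametric test for equal circular medians.

    Fisher's common-median procedure: points in each group are classified
    as lying below/above the pooled circular median and the resulting
    counts tested with a chi-square statistic on ``k - 1`` degrees of
    freedom (the CircStat ``circ_cmtest`` contract).  ``method=
    "permutation"`` instead estimates the p-value by shuffling group
    labels, which makes no asymptotic assumption.
    """
    groups = [wrap_angle(np.atleast_1d(g)) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g in groups:
        if g.size < 5:
            raise ValueError("each group needs n >= 5")
    pooled = np.concatenate(groups)
    med = circular_median(pooled)
    P = _common_median_statistic(groups, med)
    k = len(groups)
    if method == "chi2":
        p = float(_sps.chi2.sf(P, k - 1))
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        sizes = [g.size for g in groups]
        hits = 0
        valid = 0
        for _ in range(n_permutations):
            perm = rng.permutation(pooled)
            split = np.split(perm, np.cumsum(sizes)[:-1])
            try:
                Pp = _common_median_statistic(split, circular_median(perm))
            except ValueError:
                continue
            valid += 1
            if Pp >= P - 1e-12:
                hits += 1
        p = (hits + 1) / (valid + 1)
    else:
        raise ValueError(f"unknown method {method!r}")
    return {"statistic": P, "p": float(p), "df": k - 1, "median": med}


def rotate_profile(profile: PolarProfile, delta: float) -> PolarProfile:
    """Rotate a binned profile by ``delta`` radians (positive = later phase).

    The piecewise-linear periodic rate curve through the bin centres is
    resampled at the rotated centres, so rotations by arbitrary angles
    (not only multiples of the bin width) are supported.
    """
    centers = profile.centers
    # sample value at (center - delta) of the original curve
    query = wrap_angle(centers - delta)
    xp = np.concatenate([centers, centers[:1] + TWO_PI])

    def _interp(y):
        yp = np.concatenate([y, y[:1]])
        q = np.where(query < centers[0], query + TWO_PI, query)
        return np.interp(q, xp, yp)

    return PolarProfile(profile.edges.copy(), _interp(profile.rate),
                        _interp(profile.se), profile.n_obs.copy())


def rotate_and_scale(pairs):
    """Align (stimulated, control) profile pairs to a common frame.

    Each control profile is rotated so its centroid lands at angle 0 and
    scaled to peak 1; its paired stimulated profile receives the *same*
    rotation and scale.  Pairs whose control centroid is undefined or
    whose control peak is zero are excluded (with a count in the output).
    Returns the aligned pairs plus group mean +- SE per bin.
    """
    aligned = []
    excluded = 0
    for stim, ctrl in pairs:
        cen = centroid(ctrl)
        peak = float(np.max(ctrl.rate))
        if not cen.defined or peak <= 0:
            excluded += 1
            continue
        rot = -cen.angle
        ctrl_rot = rotate_profile(ctrl, rot)
        # scale measured after rotation so the aligned control peaks at 1
        scale = 1.0 / float(np.max(ctrl_rot.rate))
        aligned.append((rotate_profile(stim, rot).scaled(scale),
                        ctrl_rot.scaled(scale)))
    if not aligned:
        raise ValueError("no alignable pairs (all control centroids degenerate)")
    edges = aligned[0][0].edges
    stim_mat = np.array([p[0].rate for p in aligned])
    ctrl_mat = np.array([p[1].rate for p in aligned])
    n = len(aligned)

    def _mean_se(mat):
        mean = mat.mean(axis=0)
        se = mat.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros_like(mean)
        return PolarProfile(edges.copy(), mean, se, np.full(mean.size, n))

    return {
        "aligned_pairs": aligned,
        "stim_mean": _mean_se(stim_mat),
        "ctrl_mean": _mean_se(ctrl_mat),
        "n_units": n,
        "n_excluded": excluded,
    }


def compare_conditions(stim: PolarProfile, ctrl: PolarProfile) -> dict:
    """Stimulated-vs-control summary on matched bins.

    Returns the signed centroid shift (wrapped to ``(-pi, pi]``; negative
    = shift to an earlier phase), plus mean-rate, peak-rate and
    polar-area ratios.  Ratios are NaN when the control quantity is zero.
    """
    if stim.n_bins != ctrl.n_bins or not np.allclose(stim.edges, ctrl.edges):
        raise ValueError("profiles must share bin edges")
    cs, cc = centroid(stim), centroid(ctrl)
    if cs.defined and cc.defined:
        dtheta = float(signed_angle_diff(cs.angle, cc.angle))
    else:
        dtheta = np.nan

    def _ratio(a, b):
        return a / b if b > 0 else np.nan

    return {
        "delta_centroid": dtheta,
        "mean_rate_ratio": _ratio(cs.mean_rate, cc.mean_rate),
        "peak_rate_ratio": _ratio(cs.peak_rate, cc.peak_rate),
        "polar_area_ratio": _ratio(cs.polar_area, cc.polar_area),
        "stim": cs,
        "ctrl": cc,
    }


def group_ttests(stim_values, ctrl_values) -> dict:
    """Two-tailed unpaired t-test per metric across units.

    ``stim_values`` / ``ctrl_values`` are dicts mapping metric name to a
    per-unit array (e.g. centroid angle, mean rate, peak rate, polar
    area), mirroring how group comparisons are made across neurons or
    simulation runs rather than across bins.
    """
    out = {}
    for key in stim_values:
        a = np.asarray(stim_values[key], dtype=float)
        b = np.asarray(ctrl_values[key], dtype=float)
        t, p = _sps.ttest_ind(a, b)
        out[key] = {"t": float(t), "p": float(p),
                    "stim_mean": float(a.mean()), "ctrl_mean": float(b.mean())}
    return out
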