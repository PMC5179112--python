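"""Reduced spiking model of respiratory gating in the olfactory bulb.

A small circuit of glomerular columns — each with a mitral cell (MC) and
optionally a periglomerular (PG) and/or granule cell (GC) — is driven by
two inhomogeneous Poisson event streams per glomerulus: a *respiratory*
stream whose Gaussian rate envelope (peak ``R`` Hz, half width 30 ms)
sits at cycle phase 0 each breath, and a *sensory* stream (peak ``S``
Hz) mimicking an optical stimulus, delivered either to the recorded
MC's own glomerulus (primary mode) or to a laterally connected
neighbour's (secondary mode).

Neurons are two-variable adaptive leaky integrate-and-fire units.  The
multi-compartment biophysics is deliberately reduced to the three
features the circuit-level conclusions rest on: respiration-locked
burst firing, a post-burst refractory window (spike-triggered
adaptation), and MC peak rates below ~100 Hz (absolute refractory
period).  Synapse placement is encoded as pathway order: PG inhibition
subtracts from the MC's *tuft input* before somatic integration
(rectified at zero, emulating the tuft-proximal synapse), while GC
inhibition subtracts at the soma after input integration.  PG cells
carry both the reciprocal intraglomerular synapse and the lateral
interglomerular synapse onto connected columns; GCs are reciprocally
coupled to their own MC and laterally inhibit the other columns' MCs.
Connectivity is a star: every connected column pairs with the recorded
column.

The simulation loop is compiled with numba; subthreshold dynamics use
exact exponential decay of the synaptic traces and forward-Euler
integration of the membrane at ``dt`` (0.1 ms default).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from . import circular_stats as cstats

__all__ = [
    "InputSpec",
    "NetworkConfig",
    "Network",
    "SimResult",
    "gaussian_envelope_sigma",
    "expected_events_per_cycle",
    "gaussian_poisson_events",
    "build_network",
    "simulate",
    "polar_analysis",
    "to_session",
]

VARIANTS = ("none", "PG", "GC", "PG+GC")
HALF_WIDTH_CONVENTIONS = ("hwhm", "sigma", "half_of_full_width")


@dataclass
class InputSpec:
    """Input event statistics: peak rates (Hz) of the Gaussian envelopes.

    R : respiratory Gaussian peak Poisson rate, applied to every glomerulus.
    S : sensory Gaussian peak Poisson rate, applied to the target glomerulus.
    half_width : Gaussian half width in ms (default 30, interpreted per
        ``half_width_convention``; "hwhm" gives sigma = hw / sqrt(2 ln 2)).
    resp_rate : respiration rate in Hz (2.5 resting, 10 sniffing).
    """

    R: float = 200.0
    S: float = 0.0
    half_width: float = 30.0
    resp_rate: float = 2.5
    half_width_convention: str = "hwhm"

    def __post_init__(self):
        if self.R < 0 or self.S < 0:
            raise ValueError("R and S must be non-negative")
        if self.half_width <= 0 or self.resp_rate <= 0:
            raise ValueError("half_width and resp_rate must be positive")
        if self.half_width_convention not in HALF_WIDTH_CONVENTIONS:
            raise ValueError(f"unknown convention {self.half_width_convention!r}")

    @property
    def sigma(self) -> float:
        return gaussian_envelope_sigma(self.half_width, self.half_width_convention)

    @property
    def cycle_period(self) -> float:
        """Respiratory cycle period in ms."""
        return 1000.0 / self.resp_rate


def gaussian_envelope_sigma(half_width: float, convention: str = "hwhm") -> float:
    """Envelope SD (ms) for a stated half width under a naming convention."""
    if convention == "hwhm":
        return half_width / np.sqrt(2.0 * np.log(2.0))
    if convention == "sigma":
        return half_width
    if convention == "half_of_full_width":
        return half_width / 2.0
    raise ValueError(f"unknown convention {convention!r}")


def expected_events_per_cycle(peak: float, half_width: float = 30.0,
                              convention: str = "hwhm") -> float:
    """Analytic mean event count under one Gaussian envelope.

    ``peak * sigma * sqrt(2*pi) / 1000`` for peak in Hz and sigma in ms
    (the untruncated envelope integral); the dual bookkeeping between
    peak rates and expected events per respiration.
    """
    sigma = gaussian_envelope_sigma(half_width, convention)
    return peak * sigma * np.sqrt(2.0 * np.pi) / 1000.0


def gaussian_poisson_events(peak: float, half_width: float, center: float,
                            rng, convention: str = "hwhm") -> np.ndarray:
    """One inhomogeneous-Poisson draw under a Gaussian rate envelope.

    Event count is Poisson with the analytic envelope integral; event
    times are normal around ``center`` (ms).  ``rng`` is a
    ``numpy.random.Generator``; draws are reproducible under its seed.
    """
    if peak < 0:
        raise ValueError("peak must be >= 0")
    nu = expected_events_per_cycle(peak, half_width, convention)
    if nu == 0:
        return np.empty(0)
    n = rng.poisson(nu)
    sigma = gaussian_envelope_sigma(half_width, convention)
    return np.sort(rng.normal(center, sigma, n))


@dataclass
class NetworkConfig:
    """Circuit variant and wiring switches.

    variant : which lateral inhibitory cell classes exist.
    mode : "primary" (sensory input to the recorded MC's glomerulus) or
        "secondary" (to a connected neighbour's glomerulus).
    n_columns : number of glomerular columns *laterally connected to*
        the recorded column (0 = isolated recorded column; 1 = the base
        two-glomerulus circuit).
    gc_multiplier : GC synaptic strength as a multiple of the PG
        strength (4 default; 30/50/70/90 explored).
    secondary_inhib_weight : multiplier on the lateral inhibitory
        synapses (1 baseline; 4 and 20 model stronger lateral coupling).
    ablate : "none" | "lateral_PG" | "reciprocal_PG" — removes exactly
        one PG synapse class.
    mc_spont_rate : MC spontaneous firing floor (Hz), realised as an
        independent Poisson process that inhibition cannot remove.
    """

    variant: str = "none"
    mode: str = "primary"
    n_columns: int = 1
    gc_multiplier: float = 4.0
    etc_enabled: bool = False
    ablate: str = "none"
    secondary_inhib_weight: float = 1.0
    mc_spont_rate: float = 2.0

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if self.mode not in ("primary", "secondary"):
            raise ValueError("mode must be 'primary' or 'secondary'")
        if self.n_columns < 0:
            raise ValueError("n_columns must be >= 0")
        if self.mode == "secondary" and self.n_columns < 1:
            raise ValueError("secondary mode needs >= 1 connected column")
        if self.gc_multiplier < 1:
            raise ValueError("gc_multiplier must be >= 1")
        if self.ablate not in ("none", "lateral_PG", "reciprocal_PG"):
            raise ValueError("unknown ablation flag")
        if self.ablate != "none" and "PG" not in self.variant:
            raise ValueError(f"cannot ablate a PG synapse in variant {self.variant!r}")

    @property
    def has_pg(self) -> bool:
        return "PG" in self.variant

    @property
    def has_gc(self) -> bool:
        return "GC" in self.variant

    @property
    def total_columns(self) -> int:
        return self.n_columns + 1

    @property
    def target_column(self) -> int:
        """Column whose glomerulus receives the sensory stream."""
        return 0 if self.mode == "primary" else 1


@dataclass
class CellParams:
    """Integrate-and-fire unit constants (dimensionless voltage, ms taus).

    Defaults were set so that, under the standard respiratory drive, the
    recorded MC shows phase-0-locked burst firing with intraburst rates
    below 100 Hz, a post-burst refractory window of one to two hundred
    ms, and PG firing that saturates during the respiratory burst.
    """

    tau_m_mc: float = 10.0      # MC membrane (ms)
    tau_m_pg: float = 10.0
    tau_m_gc: float = 10.0
    tau_m_etc: float = 5.0
    tau_exc: float = 5.0        # excitatory synaptic trace
    tau_gc_in: float = 30.0     # MC->GC drive trace (slow, so bursts summate)
    tau_inh_pg: float = 50.0    # reciprocal PG inhibitory trace decay (tuft)
    tau_rise_pg: float = 5.0    # reciprocal PG inhibition rise time
    tau_inh_pg_lat: float = 250.0  # lateral (interglomerular) PG trace: slower
    tau_inh_gc: float = 40.0    # GC inhibitory trace (soma)
    tau_adapt: float = 80.0     # MC spike-triggered adaptation
    b_adapt: float = 0.35       # adaptation increment per MC spike
    ref_mc: float = 8.0         # absolute refractory (ms; intraburst < 100 Hz)
    ref_pg: float = 5.0
    ref_gc: float = 5.0
    ref_etc: float = 2.0
    thresh_etc: float = 0.8     # ETC: faster, lower-threshold relay
    w_osn_mc: float = 2.0       # OSN event -> MC tuft
    w_osn_pg: float = 3.0       # OSN event -> PG
    w_osn_etc: float = 1.5
    w_pg_recip: float = 0.6     # PG spike -> own MC tuft
    w_pg_lat: float = 0.12      # PG spike -> connected MC tuft
    cap_pg_lat: float = 0.6     # saturation of each lateral PG synapse's trace
    w_gc_recip: float = 0.010   # GC spike -> own MC soma (x gc_multiplier)
    w_gc_lat: float = 0.010     # GC spike -> connected MC soma (x gc_multiplier)
    w_mc_gc: float = 1.0        # MC spike -> own GC
    w_etc_pg: float = 0.8       # ETC spike -> local + connected PG
    w_etc_mc: float = 0.3       # ETC spike -> own MC tuft


@dataclass
class Network:
    """A buildable circuit: config plus resolved synaptic weight switches."""

    config: NetworkConfig
    params: CellParams = field(default_factory=CellParams)

    @property
    def n_columns_total(self) -> int:
        return self.config.total_columns

    def synapse_counts(self) -> dict:
        """Number of directed inhibitory synapse classes present (for
        structural checks)."""
        c = self.config
        n_lat_pairs = c.n_columns  # star: each neighbour pairs with column 0
        out = {"pg_reciprocal": 0, "pg_lateral": 0,
               "gc_reciprocal": 0, "gc_lateral": 0}
        if c.has_pg:
            if c.ablate != "reciprocal_PG":
                out["pg_reciprocal"] = self.n_columns_total
            if c.ablate != "lateral_PG":
                out["pg_lateral"] = 2 * n_lat_pairs
        if c.has_gc:
            out["gc_reciprocal"] = self.n_columns_total
            out["gc_lateral"] = 2 * n_lat_pairs
        return out


def build_network(config: NetworkConfig, params: CellParams = None) -> Network:
    """Instantiate the circuit for a validated configuration."""
    return Network(config, params or CellParams())


@dataclass
class SimResult:
    """Spike trains (ms) per cell from one run, plus the run's bookkeeping."""

    mc_spikes: list           # one array per column; [0] is the recorded MC
    pg_spikes: list
    gc_spikes: list
    etc_spikes: list
    duration: float           # ms
    dt: float
    cycle_period: float       # ms
    n_cycles: int
    config: NetworkConfig
    inputs: InputSpec
    stim_onsets: np.ndarray   # sensory stimulus onset times (ms; empty for control)

    @property
    def recorded_mc(self) -> np.ndarray:
        return self.mc_spikes[0]

    @property
    def recorded_rate(self) -> float:
        """Mean firing rate of the recorded MC (Hz)."""
        return self.recorded_mc.size / (self.duration / 1000.0)

    def phases(self, spikes=None) -> np.ndarray:
        """Respiratory phase of spike times (simulated cycles are exact)."""
        s = self.recorded_mc if spikes is None else np.asarray(spikes)
        return (s % self.cycle_period) / self.cycle_period * 2.0 * np.pi


@njit(cache=True)
def _run_kernel(n_steps, dt, C, exc_kick, spont,
                has_pg, has_gc, has_etc,
                pg_recip_on, pg_lat_on,
                tau_m_mc, tau_m_pg, tau_m_gc, tau_m_etc,
                tau_exc, tau_gc_in, tau_inh_pg, tau_rise_pg, tau_inh_pg_lat, tau_inh_gc,
                tau_adapt,
                b_adapt, ref_mc, ref_pg, ref_gc, ref_etc, thresh_etc,
                w_osn_mc, w_osn_pg, w_osn_etc,
                w_pg_recip, w_pg_lat, cap_pg_lat, w_gc_recip, w_gc_lat,
                w_mc_gc, w_etc_pg, w_etc_mc,
                mc_out, mc_n, pg_out, pg_n, gc_out, gc_n, etc_out, etc_n):
    de = np.exp(-dt / tau_exc)
    dgin = np.exp(-dt / tau_gc_in)
    dip = np.exp(-dt / tau_inh_pg)
    dipl = np.exp(-dt / tau_inh_pg_lat)
    krise = dt / tau_rise_pg
    dig = np.exp(-dt / tau_inh_gc)
    dw = np.exp(-dt / tau_adapt)
    ref_mc_s = int(ref_mc / dt)
    ref_pg_s = int(ref_pg / dt)
    ref_gc_s = int(ref_gc / dt)
    ref_etc_s = int(ref_etc / dt)

    v_mc = np.zeros(C); w_mc = np.zeros(C)
    s_exc = np.zeros(C); s_pgi = np.zeros(C); s_gci = np.zeros(C)
    y_pgi = np.zeros(C)          # alpha-filtered reciprocal inhibition (lagged)
    s_pg_lat_out = np.zeros(C)   # each PG's (saturating) lateral synapse trace
    v_pg = np.zeros(C); s_pg_in = np.zeros(C)
    v_gc = np.zeros(C); s_gc_in = np.zeros(C)
    v_etc = np.zeros(C); s_etc_in = np.zeros(C)
    last_mc = np.full(C, -10**9); last_pg = np.full(C, -10**9)
    last_gc = np.full(C, -10**9); last_etc = np.full(C, -10**9)

    for t in range(n_steps):
        tm = t * dt
        for c in range(C):
            # trace decay
            s_exc[c] *= de
            s_pgi[c] *= dip
            y_pgi[c] += krise * (s_pgi[c] - y_pgi[c])
            s_pg_lat_out[c] *= dipl
            s_gci[c] *= dig
            s_gc_in[c] *= dgin
            s_etc_in[c] *= de
            s_pg_in[c] *= de
            w_mc[c] *= dw
            # afferent events
            e = exc_kick[c, t]
            if e > 0.0:
                s_exc[c] += e * w_osn_mc
                if has_pg:
                    s_pg_in[c] += e * w_osn_pg
                if has_etc:
                    s_etc_in[c] += e * w_osn_etc
        # ETC relay (excites local + partner PG, own MC tuft)
        if has_etc:
            for c in range(C):
                v_etc[c] += (dt / tau_m_etc) * (-v_etc[c] + s_etc_in[c])
                if v_etc[c] >= thresh_etc and t - last_etc[c] >= ref_etc_s:
                    v_etc[c] = 0.0
                    last_etc[c] = t
                    if etc_n[c] < etc_out.shape[1]:
                        etc_out[c, etc_n[c]] = tm
                        etc_n[c] += 1
                    s_exc[c] += w_etc_mc
                    if has_pg:
                        s_pg_in[c] += w_etc_pg
                        if c == 0:
                            for j in range(1, C):
                                s_pg_in[j] += w_etc_pg
                        else:
                            s_pg_in[0] += w_etc_pg
        # PG cells
        if has_pg:
            for c in range(C):
                v_pg[c] += (dt / tau_m_pg) * (-v_pg[c] + s_pg_in[c])
                if v_pg[c] >= 1.0 and t - last_pg[c] >= ref_pg_s:
                    v_pg[c] = 0.0
                    last_pg[c] = t
                    if pg_n[c] < pg_out.shape[1]:
                        pg_out[c, pg_n[c]] = tm
                        pg_n[c] += 1
                    if pg_recip_on:
                        s_pgi[c] += w_pg_recip
                    if pg_lat_on:
                        # lateral output saturates (finite receptor pool)
                        s_pg_lat_out[c] += w_pg_lat
                        if s_pg_lat_out[c] > cap_pg_lat:
                            s_pg_lat_out[c] = cap_pg_lat
        # GC cells (driven by own MC spikes from the previous steps)
        if has_gc:
            for c in range(C):
                v_gc[c] += (dt / tau_m_gc) * (-v_gc[c] + s_gc_in[c])
                if v_gc[c] >= 1.0 and t - last_gc[c] >= ref_gc_s:
                    v_gc[c] = 0.0
                    last_gc[c] = t
                    if gc_n[c] < gc_out.shape[1]:
                        gc_out[c, gc_n[c]] = tm
                        gc_n[c] += 1
                    s_gci[c] += w_gc_recip
                    if c == 0:
                        for j in range(1, C):
                            s_gci[j] += w_gc_lat
                    else:
                        s_gci[0] += w_gc_lat
        # mitral cells: PG gates the tuft input (rectified), GC the soma
        for c in range(C):
            lat = 0.0
            if c == 0:
                for j in range(1, C):
                    lat += s_pg_lat_out[j]
            else:
                lat = s_pg_lat_out[0]
            tuft = s_exc[c] - y_pgi[c] - lat
            if tuft < 0.0:
                tuft = 0.0
            drive = tuft - s_gci[c] - w_mc[c]
            v_mc[c] += (dt / tau_m_mc) * (-v_mc[c] + drive)
            fired = False
            if v_mc[c] >= 1.0 and t - last_mc[c] >= ref_mc_s:
                fired = True
            elif spont[c, t] == 1 and t - last_mc[c] >= ref_mc_s:
                fired = True   # spontaneous floor: forced, inhibition-proof
            if fired:
                v_mc[c] = 0.0
                last_mc[c] = t
                w_mc[c] += b_adapt
                if mc_n[c] < mc_out.shape[1]:
                    mc_out[c, mc_n[c]] = tm
                    mc_n[c] += 1
                if has_gc:
                    s_gc_in[c] += w_mc_gc


def _event_steps(events, t0, dt, n_steps, out, col):
    idx = np.floor((np.asarray(events) - t0) / dt).astype(np.int64)
    idx = idx[(idx >= 0) & (idx < n_steps)]
    np.add.at(out[col], idx, 1.0)


def simulate(network: Network, inputs: InputSpec, n_cycles: int = 40,
             dt: float = 0.1, seed: int = 0, n_stim_phases: int = 12,
             warmup_cycles: int = 1, paired_control: bool = True):
    """Run the circuit for ``n_cycles`` breaths; return (stimulated, control).

    The control run receives only respiratory events at every
    glomerulus; the stimulated run additionally delivers one sensory
    Gaussian per cycle to the target glomerulus, with onset phases
    cycling deterministically through ``n_stim_phases`` evenly spaced
    phases so every phase bin accumulates equal trials.  Sensory
    envelope peaks sit ``half_width`` ms after the onset (the rising
    half width is assigned to the onset time); respiratory envelopes
    peak at cycle phase 0.

    Both runs share the same respiratory-event and spontaneous-spike
    realisations (common random numbers), so their difference isolates
    the effect of the sensory stream.  A warmup cycle before t = 0 is
    simulated and discarded.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    if dt > 1.0:
        raise ValueError("dt must be <= 1 ms")
    cfg = network.config
    prm = network.params
    T = inputs.cycle_period
    C = cfg.total_columns
    if cfg.target_column >= C:
        raise ValueError("secondary mode requires a connected column")
    t0 = -warmup_cycles * T
    duration = n_cycles * T
    n_steps = int(round((duration - t0) / dt))

    ss = np.random.SeedSequence(seed)
    resp_rng = np.random.default_rng(ss.spawn(1)[0])
    spont_rng = np.random.default_rng(ss.spawn(1)[0])
    sens_rng = np.random.default_rng(ss.spawn(1)[0])

    # respiratory events: one Gaussian per cycle per glomerulus, peak at phase 0
    kick = np.zeros((C, n_steps))
    for c in range(C):
        for k in range(-warmup_cycles, n_cycles + 1):
            ev = gaussian_poisson_events(inputs.R, inputs.half_width, k * T,
                                         resp_rng, inputs.half_width_convention)
            _event_steps(ev, t0, dt, n_steps, kick, c)
    # spontaneous MC spikes (shared by both runs)
    spont = np.zeros((C, n_steps), dtype=np.uint8)
    for c in range(C):
        n_sp = spont_rng.poisson(cfg.mc_spont_rate * (duration - t0) / 1000.0)
        st = np.floor(spont_rng.uniform(0, n_steps, n_sp)).astype(np.int64)
        spont[c, st] = 1
    # sensory schedule
    stim_onsets = np.array([k * T + (k % n_stim_phases) / n_stim_phases * T
                            for k in range(n_cycles)])
    kick_stim = kick.copy()
    for onset in stim_onsets:
        ev = gaussian_poisson_events(inputs.S, inputs.half_width,
                                     onset + inputs.half_width,
                                     sens_rng, inputs.half_width_convention)
        _event_steps(ev, t0, dt, n_steps, kick_stim, cfg.target_column)

    def _one(kk, onsets):
        max_mc = int((duration - t0) / prm.ref_mc) + 16
        max_i = int((duration - t0) / 2.0) + 16
        mc_out = np.zeros((C, max_mc)); mc_n = np.zeros(C, dtype=np.int64)
        pg_out = np.zeros((C, max_i)); pg_n = np.zeros(C, dtype=np.int64)
        gc_out = np.zeros((C, max_i)); gc_n = np.zeros(C, dtype=np.int64)
        etc_out = np.zeros((C, max_i)); etc_n = np.zeros(C, dtype=np.int64)
        sec_w = cfg.secondary_inhib_weight
        _run_kernel(
            n_steps, dt, C, kk, spont,
            cfg.has_pg, cfg.has_gc, cfg.etc_enabled,
            cfg.ablate != "reciprocal_PG", cfg.ablate != "lateral_PG",
            prm.tau_m_mc, prm.tau_m_pg, prm.tau_m_gc, prm.tau_m_etc,
            prm.tau_exc, prm.tau_gc_in, prm.tau_inh_pg, prm.tau_rise_pg,
            prm.tau_inh_pg_lat, prm.tau_inh_gc, prm.tau_adapt,
            prm.b_adapt, prm.ref_mc, prm.ref_pg, prm.ref_gc, prm.ref_etc,
            prm.thresh_etc,
            prm.w_osn_mc, prm.w_osn_pg, prm.w_osn_etc,
            prm.w_pg_recip, prm.w_pg_lat * sec_w, prm.cap_pg_lat * sec_w,
            prm.w_gc_recip * cfg.gc_multiplier,
            prm.w_gc_lat * cfg.gc_multiplier * sec_w,
            prm.w_mc_gc, prm.w_etc_pg, prm.w_etc_mc,
            mc_out, mc_n, pg_out, pg_n, gc_out, gc_n, etc_out, etc_n)

        def _collect(out, n):
            trains = []
            for c in range(C):
                s = out[c, :n[c]] + t0
                trains.append(s[s >= 0.0])   # drop warmup
            return trains

        res = SimResult(_collect(mc_out, mc_n), _collect(pg_out, pg_n),
                        _collect(gc_out, gc_n), _collect(etc_out, etc_n),
                        duration, dt, T, n_cycles, cfg, inputs, onsets)
        if res.recorded_rate > 500.0:
            raise RuntimeError(
                f"numerical instability: recorded MC at {res.recorded_rate:.0f} Hz")
        return res

    stim_res = _one(kick_stim, stim_onsets)
    ctrl_res = _one(kick, np.empty(0))
    return stim_res, ctrl_res


def to_session(result: SimResult, block_center=(300.0, 300.0),
               field_size=(600.0, 600.0), side: float = 100.0):
    """Package a simulated run as an analysis :class:`Session`.

    The sensory stimulus schedule becomes the stimulus log (every
    stimulus targets one fixed block, as in the single-glomerulus
    experiments) and the exact simulated cycle provides the phase map,
    so simulated and recorded data flow through identical analysis code.
    """
    import pandas as pd

    from .receptive_field_mapping import STIM_COLUMNS, Session
    from .respiration_phase import PhaseMap

    T = result.cycle_period
    peaks = np.arange(0.0, result.duration + T / 2, T)
    pmap = PhaseMap(peaks, peaks[:-1] + T / 2)
    onsets = np.asarray(result.stim_onsets, dtype=float)
    dur = 2.0 * result.inputs.half_width
    stim = pd.DataFrame({
        "x": block_center[0], "y": block_center[1], "side": side,
        "onset": onsets, "duration": dur, "onset_phase": np.nan,
    }, columns=STIM_COLUMNS)
    return Session(result.recorded_mc, stim, pmap, field_size)


def polar_analysis(result_pair, n_bins: int = 12, alpha: float = 0.05):
    """Phase-binned polar profiles and centroid comparison for a run pair.

    Bins the recorded MC's spikes against the known simulated cycle
    (per-cycle rates, SE across cycles) and delegates the centroid /
    rate / area comparison to the circular-statistics module.

    A centroid *shift* is only meaningful when the control condition has
    a defined preferred phase, so — as in the experimental analysis,
    where every included unit first passed Rayleigh's test for
    significant respiratory coupling — ``coupled`` reports whether the
    control spike phases reject uniformity at ``alpha``; centroid-shift
    consumers should treat uncoupled runs as having no measurable shift.
    """
    stim, ctrl = result_pair
    if stim.n_cycles < 20:
        raise ValueError("need >= 20 cycles per condition for stable profiles")

    def _profile(res):
        T = res.cycle_period
        per_cycle = []
        s = res.recorded_mc
        for k in range(res.n_cycles):
            sel = s[(s >= k * T) & (s < (k + 1) * T)]
            per_cycle.append((sel % T) / T * 2.0 * np.pi)
        expo = (T / n_bins) / 1000.0   # seconds per bin per cycle
        return cstats.bin_polar_trials(per_cycle, n_bins, trial_exposure=expo)

    p_stim, p_ctrl = _profile(stim), _profile(ctrl)
    comparison = cstats.compare_conditions(p_stim, p_ctrl)
    if ctrl.recorded_mc.size >= 4:
        ctrl_p = cstats.rayleigh_test(ctrl.phases())["p"]
    else:
        ctrl_p = 1.0
    return {"stim_profile": p_stim, "ctrl_profile": p_ctrl,
            "ctrl_rayleigh_p": ctrl_p, "coupled": ctrl_p < alpha,
            **comparison}
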