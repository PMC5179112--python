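# respigate

Respiration gates how the olfactory bulb responds to sensory input:
mitral/tufted cells (MTCs) burst at the inhalation→exhalation
transition, and stimuli arriving at different phases of the breath are
not processed equally. `respigate` is a Python package for
electrophysiologists and modellers studying this phenomenon. It
implements, in one place:

- **Respiratory phase mapping** — segmenting a thermistor trace into
  cycles, with the trace peak defined as phase 0 (≡ 2π) and the trough
  as π, and each half-cycle independently linearly scaled to angle θ.
- **Phase-conditioned receptive-field mapping** — composite heatmaps of
  responses to pseudo-random 100×100 µm single-block light stimuli,
  with the phase-matched control activity (mean + k·SD at the stimulus
  onset phase) subtracted, overlapping blocks averaged, and excitatory /
  inhibitory regions of interest extracted.
- **Circular statistics** — polar firing profiles, the centroid (vector
  mean; angle = preferred phase, magnitude = resultant length R̄),
  Rayleigh's test (z = n·R̄²), Fisher's multi-sample equal-medians test,
  group rotation/normalization, and stimulated-vs-control comparisons
  (Δcentroid wrapped to (−π, π], negative = earlier phase; polar area
  ½·Σ rᵢ²·Δθ).
- **A diagnostic synthetic-data generator** — artificial respiration,
  spike trains phase-locked through periodic Gaussian rate bumps, and
  full block-stimulation sessions with planted excitatory and
  suppressive sites, so every analysis stage is validated against known
  ground truth.
- **A reduced spiking olfactory-bulb circuit** — glomerular columns of
  adaptive integrate-and-fire mitral, periglomerular (PG) and granule
  (GC) cells driven by Gaussian-envelope Poisson event streams (peak
  rates R for respiration, S for the light-like stimulus, half width
  30 ms), reproducing PG-mediated phase gating, GC near-inertness at
  baseline weight, multi-column suppression to the 2 Hz spontaneous
  floor, and the null effect of single-column secondary input.
- **A campaign manager** — deterministic enumeration and parallel
  execution of R×S×variant×mode sweeps (the shipped specs reproduce the
  published 1444/11552/5776/1200/2888-run designs), with resumable
  results and Δcentroid/peak-rate summary tables.

## Worked example

Validate the analysis chain on synthetic data with a known preferred
phase, then measure gating in the circuit model:

```python
import numpy as np
from respigate import bulb_network as bn
from respigate import circular_stats as cs
from respigate import respiration_phase as rp
from respigate import synthetic_data as sd

# a 2-minute synthetic respiration trace (671 +- 121 ms periods)
trace, true_map = sd.synth_respiration(mean_period=671, sd_period=121,
                                       duration=120, seed=1)
detected = rp.detect_extrema(trace)
print(rp.cycle_statistics(detected))

# spikes locked to the trough (angle pi), analysed blind to the truth
spec = sd.PhaseLockSpec(center_angle=np.pi, width=0.4,
                        baseline_rate=2, peak_rate=40)
spikes = sd.synth_phase_locked_spikes(spec, true_map, seed=2)
angles = rp.assign_phase(spikes, detected)
c, r = cs.centroid(angles), cs.rayleigh_test(angles)
print(c.angle, c.magnitude, r["z"], r["p"])

# periglomerular gating in the two-column circuit
net = bn.build_network(bn.NetworkConfig(variant="PG", n_columns=1))
pair = bn.simulate(net, bn.InputSpec(R=200, S=240), n_cycles=40, seed=3)
res = bn.polar_analysis(pair)
print(res["delta_centroid"], res["stim"].peak_rate, res["ctrl"].peak_rate)
```

This prints (formatted):

```
detected 176 cycles, period 676 +- 107 ms (1.48 Hz)
964 spikes; centroid angle 3.164 rad (truth 3.142), resultant 0.69,
Rayleigh z=449, p=1.3e-226
PG circuit, R=200, S=240: delta centroid -0.48 rad,
stim peak 16 Hz vs control 14 Hz
```

The recovered centroid sits within 0.02 rad of the planted angle, and
the PG circuit shifts stimulated activity ~0.5 rad toward *earlier*
phases of the breath — the gating signature: sensory input is effective
before the respiratory burst and suppressed after it.

## Command line

```bash
respigate diagnose --seed 1 --out session.h5        # synthetic session + truth sidecar
respigate grid --spec desk_fig7_slice --seed 0 --out runs.csv --workers 4
respigate summarize runs.csv --csv summary.csv
```

Shipped campaign specs: `rs_grid` (38×38 R×S points), `full_variants`,
`gc_levels`, `fine_grid`, `secondary_inhibition`, and the desk-scale
`desk_fig7_slice`.

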