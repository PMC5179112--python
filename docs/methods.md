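# Methods

`respigate` couples an electrophysiology analysis chain — phase-resolved
optogenetic receptive-field mapping of mitral/tufted cells (MTCs) against
the respiratory cycle — with a reduced spiking model of the olfactory
bulb circuit that reproduces respiration-driven gating of sensory input.
This note records the models, the numerical choices, and the limits of
what the synthetic validation shows.

## Respiratory phase model

A thermistor-like respiration trace is segmented into cycles by
moving-average smoothing (25 ms) followed by local-extremum search with
a minimum peak separation (default 250 ms, safe for 1–2.5 Hz anesthetized
breathing with a ~30 ms sensor response) and a prominence gate at 10% of
the trace range. Extrema are pruned to a strict peak/trough/peak
alternation. The phase convention is: trace **peak = 0 (≡ 2π), trough =
π**, and each half cycle is *independently* linearly scaled to angle, so
inhalation and exhalation halves of unequal duration each span half a
turn. Phase assignment is exact piecewise-linear interpolation; a 1 ms
lookup table (`PhaseMap.phase_table`) is available for parity with
table-based pipelines but is never the primary path. Which thermistor
extremum corresponds to end-inhalation is labeling metadata, not
hard-coded: the trace peak is always angle 0.

## Receptive-field mapping

Stimuli are single 100×100 µm light blocks (25 px at the 4 µm projected
pixel size) flashed one at a time for 100 or 200 ms with a 200 ms
inter-stimulus interval, placed pseudo-randomly without repeats.
For each stimulus:

- **response window** = onset to 50 ms before light-off;
- **control window** = the stimulus-free interval ending at onset,
  beginning at least 50 ms after the previous light-off, and truncated
  to the length of the stimulus's own response window. The truncation
  matters: control and response rates are then exchangeable under the
  null, so the control SD calibrates the subtraction. Without it, SDs
  estimated from ~150 ms windows systematically under-estimate the rate
  granularity of 50 ms response windows and the type-I error inflates.
- the stimulus deposits `response_rate − (control_mean + k·SD)` over its
  footprint, where mean and SD come from the phase bin of the stimulus
  **onset** phase (windows span a range of angles; binning by start
  phase is a documented approximation). `k` defaults to 1.5 and is
  per-session configurable (0–10): strongly coupled cells separate at
  0–3 SD, highly variable cells may need ~10.

Overlapping deposits are averaged per pixel; smoothing is a *normalized*
Gaussian over covered pixels only (σ = 4 px for excitatory maps, 10 px
for inhibitory maps), so unexplored pixels neither receive values nor
drag ROI edges. Pixels never covered are NaN, never 0.

**ROI extraction.** Excitatory ROIs are connected components above
threshold on the subtracted map; inhibitory ROIs are components *below*
threshold (default 8 Hz, with the 5 Hz variant exposed — both are in
use) on an **unsubtracted** map ("dark regions"). Two defaults protect
against speckle: `min_coverage = 5` (the mapping strategy relies on
overlapping blocks sampling each region many times; a pixel averaged
over one or two deposits cannot support a significance claim) and
`min_pixels = 120`, the area of the smallest glomerulus (50 µm diameter)
at 4 µm pixels. Under these defaults, stimulus-free synthetic sessions
(600 stimuli on a 600×600 µm field, a respiration-locked cell at ~17 Hz
mean rate) yield zero excitatory ROIs at k = 1.5 in ≥ 95% of seeds.

## Circular statistics

Angles use equal-width bins tiling [0, 2π) (12 for profiles, 6 for
condition comparisons). The centroid is the vector mean; its angle is
the preferred phase and its magnitude the mean resultant length.
Zero-resultant samples are flagged `defined=False` rather than given an
arbitrary angle. Summary metrics per profile: peak bin rate, mean rate,
and **polar area** defined as ½·Σ rᵢ²·Δθ (the area enclosed by the
piecewise-constant polar curve, Hz²) — the polar curve itself is never
interpolated for this quantity.

- **Rayleigh test**: z = n·R̄², p from the standard small-sample-corrected
  approximation `exp(√(1+4n+4(n²−R²)) − (1+2n))`. Type-I error at
  α = 0.05 verified within [0.03, 0.07] on 2000 uniform samples (n = 50).
- **Equal-medians test** (circular Kruskal–Wallis analogue): Fisher's
  common-median chi-square on counts below the pooled circular median,
  k−1 degrees of freedom, with a label-permutation alternative. A
  perfectly balanced antipodal pooled sample has no usable median and
  raises with a diagnostic. The chi-square approximation is known to
  drift from the permutation null for groups under ~25 observations
  (p discrepancies up to ~0.3 from the count lattice); with groups of
  40+, the two agree within Monte-Carlo error.
- **Group alignment**: each unit's control profile is rotated so its
  centroid sits at angle 0 and scaled to control peak 1 (the scale is
  measured after rotation so the aligned control peaks at exactly 1);
  the paired stimulated profile gets the same rotation and scale.
  Rotation of a binned profile resamples the periodic piecewise-linear
  rate curve, so arbitrary rotation angles are supported.
- **Condition comparison**: signed centroid shift wrapped to (−π, π]
  (negative = earlier phase), plus mean-rate, peak-rate and polar-area
  ratios; group-level two-tailed unpaired t-tests act across units,
  never across bins.
- Both centroid flavours are available — raw spike-angle centroid and
  rate-weighted bin centroid; `polar_analysis` uses the binned form for
  profiles and the raw form for coupling tests, and consumers log which
  they used.

## Synthetic diagnostic data

The generator exists so every analysis stage can be validated against
known ground truth with no recorded data.

- **Respiration**: per-cycle periods from a normal truncated at ±2.5 SD
  (defaults 671 ± 121 ms, the anesthetized population statistics; 400 ms
  for the 2.5 Hz model regime); the trace is the cosine of the
  generative phase, and the exact landmark times are returned.
- **Spikes**: an inhomogeneous Poisson process whose rate is defined in
  the *phase* domain (baseline + circular-Gaussian bump at a chosen
  angle) and realised in time by thinning, so irregular cycles warp the
  bump exactly as the phase-based analysis assumes.
- **Sessions**: pseudo-random non-repeating block placement (uniform
  over the field minus a half-block margin, optional minimum spacing of
  consecutive centres), 100/200 ms durations, 200 ms ISI. Planted
  excitatory sites add Poisson(gain × overlap) spikes at a 10 ms latency
  when hit during their responsive phase interval; planted suppressive
  sites thin baseline spikes by suppression × overlap during the
  stimulus, at all phases by default. Default desk scale is 600 stimuli
  (~6 min equivalent) against the full-scale ~5,800; tests that need
  tighter coverage statistics state their own sizes.

Everything is byte-reproducible under a seed. What passing diagnostics
do **not** show about real data: electrode noise, spike-sorting errors,
multi-unit contamination, drift in respiration shape, and optical
scattering are all absent; the generator validates the *analysis code*,
not robustness to acquisition artefacts.

## Reduced bulb circuit

Glomerular columns (a glomerulus, its mitral cell, and optionally a
periglomerular (PG) and granule (GC) cell) are connected in a star: each
of `n_columns` neighbours pairs with the recorded column. Inputs are
Gaussian-envelope Poisson event streams (half width 30 ms, read as
half-width-at-half-maximum, σ ≈ 25.48 ms; `sigma` and half-of-full-width
conventions are switchable because the term is ambiguous — expected
events per cycle are reported for whichever convention is active, e.g.
peak 200 Hz → 12.8 events/cycle). The respiratory stream (peak R Hz)
peaks at cycle phase 0 on every glomerulus; the sensory stream (peak
S Hz) goes to the recorded column (primary mode) or a neighbour
(secondary mode), one stimulus per cycle with onsets cycling through 12
evenly spaced phases and the envelope peak sitting one half-width after
onset.

Cells are two-variable adaptive leaky integrate-and-fire units
(dimensionless threshold 1, exact exponential trace decay,
forward-Euler membrane update at dt = 0.1 ms). The reduction keeps the
three features the circuit conclusions rest on: respiration-locked
bursts, a post-burst refractory window (spike-triggered adaptation,
increment 0.35, τ = 80 ms), and bounded intraburst rates (absolute
refractory 8 ms → < 125 Hz). Synapse *placement* is encoded as pathway
order:

- **PG inhibition acts on the tuft input before somatic integration**
  (`tuft = max(0, excitation − PG)`), implementing the tuft-proximal
  reciprocal synapse. The reciprocal trace rises with a short 5 ms lag
  and decays with τ = 50 ms. Because the PG is driven by the same
  afferent events as the MC but integrates to threshold first, early
  sensory events pass and later ones are clipped — and a PG already
  primed by the respiratory burst blocks stimuli arriving just after
  the burst. This is the gating mechanism, and ablating the reciprocal
  synapse weakens the centroid shift far more than ablating the lateral
  one.
- **The lateral (interglomerular) PG synapse saturates**: each PG's
  lateral output trace is capped (0.6, τ = 250 ms). The cap is what
  makes single-column lateral effects bounded — once the neighbour's PG
  is driven to saturation by respiration, extra sensory drive adds
  nothing — while several columns still sum to eliminate activity.
- **GC inhibition subtracts at the soma after input integration**; GCs
  are driven by their own MC through a slow (30 ms) trace so bursts
  summate, and their weight is `0.01 × gc_multiplier` (default ×4, with
  30–90 exposed). At ×4 the GC path is deliberately near-inert,
  matching the observation that GC-only circuits behave like
  no-inhibition circuits at baseline coupling.
- The MC's 2 Hz spontaneous floor is an independent Poisson process
  merged in the kernel as forced spikes that inhibition cannot delete —
  so lateral inhibition can drive evoked activity down *to* the floor
  but never below it.
- Optional external tufted cell: a faster (τ = 5 ms), lower-threshold
  (0.8) relay from the afferent stream onto local and neighbouring PGs
  and the local tuft.

Stimulated and control runs share the respiratory-event and
spontaneous-spike realisations (common random numbers), so their
difference isolates the sensory stream's effect; with S = 0 the pair is
bit-identical. One warmup cycle is simulated and discarded. A run whose
recorded-MC rate exceeds 500 Hz aborts as numerically implausible.

**Centroid-shift validity.** A shift of the preferred phase is only
meaningful when the control condition *has* a preferred phase, so
`polar_analysis` reports whether the control spike angles reject
uniformity (Rayleigh, α = 0.05) — the same inclusion rule applied to
recorded units — and sweep maxima over Δcentroid use only coupled
points. Rate metrics use all points.

## Simulation campaigns

Campaigns are Cartesian products over R, S, variants, modes, GC levels,
column counts, respiration rates and lateral weights, with inclusive
endpoints (20:20:760 → 38 values, hence 38² = 1444 R×S combinations;
× 4 variants × 2 modes = 11552; × GC levels {30,50,70,90} = 5776;
R 300:5:495 × S 50:5:195 = 1200; × {PG, GC} secondary = 2888 — all
reproduced by the shipped specs without running anything). Run-count
bookkeeping counts unique parameter points; each point is replicated
over seeds (default 3) with per-run seeds derived from
`SeedSequence((base, point, seed_index))`, so results are identical for
any worker count or execution order, and campaigns resume from partial
tables. Default 40 cycles per run (16 s simulated at 2.5 Hz) keeps a
full desk-scale sweep in minutes on one core; the summary flags the
(R, S) region where |Δcentroid| reaches a reference shift (default
0.75 rad, the magnitude of the mean in vivo gating effect).

## Known limitations

- The model reproduces: the 2 Hz spontaneous floor; negative
  (earlier-phase) centroid shifts under PG inhibition that grow with
  sensory strength; GC(×4) ≈ no-inhibition; monotone suppression with
  column count reaching the spontaneous floor by ~6 connected columns
  at R = 200, S = 100; and bounded single-column secondary effects
  (|Δcentroid| ≤ 0.25 rad, |Δpeak-rate| ≤ 6 Hz over 20–720 Hz inputs).
- It does **not** reproduce the increase in stimulated-profile
  concentration at 10 Hz sniffing under PG inhibition: in this
  reduction, parameter regimes strong enough to sharpen the 10 Hz
  profile also abolish the control respiratory burst in the two-column
  circuit, which contradicts the control behaviour the rest of the
  model is built on. The published effect likely depends on biophysics
  (sustained PG firing, NMDA kinetics) that the two-variable units
  deliberately omit. At 10 Hz our PG circuit instead shifts stimulated
  activity to *later* phases.
- Without lateral inhibition, the refractory mechanism alone produces
  near-zero to slightly positive shifts at extreme sensory drive rather
  than weak negative ones.
- The Fisher common-median chi-square is an approximation; use the
  permutation option for groups under ~25 observations.
- Type-I control of the mapping pipeline holds for firing regimes near
  the recorded population (~4–70 Hz) and coverage ≥ 5 deposits/pixel;
  very sparse cells (< 5 Hz flat) with 50 ms windows remain rate-
  granularity-limited and need a larger k, exactly as per-neuron k
  tuning was used in practice.
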