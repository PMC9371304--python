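# Methods

## Compartment model

The simulator describes one thin astrocytic process apposed to a
hippocampal synapse as a well-mixed two-compartment system (cytosol and
ER, volume ratio ρ = 0.15) with five continuous state variables —
cytosolic Ca²⁺, ER Ca²⁺, IP₃, and Ca²⁺ bound to a kinetic buffer in
each compartment (all μM) — plus the discrete Markov states of an IP₃R
cluster.  Continuous variables advance by explicit Euler at a fixed
50 μs step; channel gating advances by per-subunit Markov jumps (at
most one transition per subunit per step, exit probabilities asserted
≪ 1).  Because gating is the only stochastic term, the nominal
Euler–Maruyama update degenerates to Euler plus jumps.  ER fluxes are
expressed on the cytosolic concentration scale and mirrored into the ER
divided by ρ, so that with the plasma-membrane terms disabled the total
Ca²⁺ ledger `c + b_cyt + ρ(c_ER + b_ER)` closes exactly (tested).

### Fluxes

- **IP₃R cluster**: N = 20 channels, each three independent
  eight-state De Young–Keizer subunits (one IP₃ site, one activating
  and one inhibitory Ca²⁺ site); a channel conducts when all three
  subunits are in the active state (IP₃ and activating Ca²⁺ bound,
  inhibitory site free).  Flux = ν · (open fraction) · (c_ER − c).
  Subunit rate constants are the canonical ones for this scheme; the
  scheme itself is configuration (any 8-state variant can be loaded
  from the parameter file).
- **SERCA / PMCA**: Hill n = 2 pumps.  The PMCA is parameterized by
  forward/backward binding rates, giving the operational affinity
  √(k_b/k_f); this makes "adjust the backward rate" a meaningful
  pathological lever.  A constant membrane influx balances the PMCA at
  rest.
- **IP₃ turnover**: mGluR production is a Hill function (slope 1) of
  total agonist (synaptic glutamate plus bath DHPG, acting through the
  same receptor pool); PLCδ adds Ca²⁺-activated production;
  5-phosphatase (first-order) and Ca²⁺-activated 3-kinase degrade.
- **Buffers**: explicit on/off kinetics in both compartments rather
  than a rapid-buffer approximation, because event rise times of tens
  of milliseconds are themselves validation targets.

### Resting state

The fixed point decouples: the PMCA/influx balance fixes resting
cytosolic Ca²⁺ (≈ 60 nM for the defaults), the IP₃
production/degradation balance then fixes resting IP₃ (≈ 5 nM), and
the SERCA/leak/IP₃R balance fixes resting ER Ca²⁺ (≈ 400 μM — the high
luminal load of the process).  `resting_state` evaluates this closed
form, verifies the residual, and raises on parameter sets with no
stable rest (e.g. influx exceeding pump capacity).  Negative Euler
excursions during sharp events are clipped to zero with a logged
warning; NaN/Inf aborts with a diagnostic.

## Release machinery

Sensor occupancies are pool-level expectations (mean-field): Syt4 is a
two-state binder (k_d = k_off/k_on = 22 μM, fast k_on), Syt7 a
six-state sequential chain (five sites, per-site k_d = 15 μM, slow
k_on) with statistical factors (5k_on, 4k_on, …) and a cooperativity
factor b = 0.55 multiplying the off-rate per successive bound site;
fusion proceeds from the Ca²⁺-bound (Syt4) or fully bound (Syt7)
state.  Stochasticity enters only at the release draw — a vesicle is
released when instantaneous rate × 50 μs exceeds a uniform variate, at
most one per mode per step — and at the binomial pool transitions.

Vesicles occupy six integer pools: docked (capacity 20), mobile, and a
fused → reacidifying chain per pathway.  Kiss-and-run recycles fast
(endocytosis 2 s⁻¹, reacidification 0.5 s⁻¹), full fusion slowly
(0.25 s⁻¹, 0.1 s⁻¹); recycled vesicles always re-enter the mobile pool
and re-dock at 0.12 s⁻¹ while free docking sites remain.  Total vesicle
number is conserved exactly at every step (asserted in the stepping
code and tested).

The clamped-Ca²⁺ characterization (`characterize_clamped`) integrates
the coupled sensor/pool expectations with an adaptive solver from fully
unbound sensors and full pools; Hill fits of the peak rates recover
k_d ≈ 23 μM (Syt4) and ≈ 16 μM (Syt7) over a 1–200 μM ladder, and
Syt4's time-to-peak falls from ~15 ms to ~2 ms across that ladder while
Syt7's stays in the hundreds of milliseconds — the fast-synchronous vs
slow-asynchronous division of labor.

## Aβ conditions

Both pathologies are parameter transforms with an idempotency guard and
field-wise minimality (tested): the mGluR condition halves the
half-activation and doubles the maximal production; the PMCA condition
multiplies the backward rate by a factor found by a bracketed
one-dimensional search so that the *fitted* affinity of the
steady-state flux curve halves (the published observation is the fitted
shift, not a rate factor; for a Hill n = 2 pump the search lands at
4.0).  The weakened pump doubles resting cytosolic Ca²⁺ and raises the
ER load, which reproduces elevated spontaneous activity and larger,
longer events.

## Event statistics

- **Detection**: local maxima above 300 nM with prominence ≥ half the
  threshold (events riding on elevated baselines are referenced to
  their own base; overlapping events split at the valley).  Widths at
  half prominence-referenced height; 20→80% rise and peak→36.8% decay
  with linear interpolation; unresolved limbs are flagged and excluded
  from kinetic averages.
- **Percentage response**: trapezoidal AUC over the stimulation window
  divided by the matching pre-stimulus window.
- **Synchrony**: the published recipe (inter-event intervals per
  reference event → normalized phases → circular projection →
  1 − Var(Z)) is ambiguous in two places: the variance of complex
  unit-modulus samples, and which intervals form the phase vector.
  Var(Z) is taken as the circular variance, making the score the
  squared resultant length.  For the intervals, the adopted reading
  wraps each time difference to a reference event by the probed
  inter-event interval I and maps it to a phase (Δt mod I)/I — a
  stroboscopic phase-locking score, evaluated per probed interval
  (default: the mean within-trial interval).  This is the only reading
  we found that satisfies both published limits *exactly*: trains
  aligned across trials at spacing I give 1, and fully random trains
  give → 0 at any I.  (A literal "normalize by the maximum interval"
  reading scores aligned trains far below 1.)  A brute-force
  reimplementation serves as the oracle in the tests.
- **JPSTH cross-correlation**: Ca²⁺ and release events are binned per
  trial at the 100 ms correlation window; the joint histogram across
  trials is shuffle-corrected by the marginal-PSTH outer product and
  normalized by the bin-count standard deviations; the diagonal is the
  within-window correlation profile and its maximum over the 11 s
  signal is the peak.  Identical trains score exactly 1, independent
  trains ~0 (both tested).  Zero-variance bins are NaN, never 0.
- **Bootstrap**: s.d. of a statistic over resamples with replacement
  (defaults 100 × 1000).

## Execution and reproducibility

A trial is fully determined by (parameters, protocol, base seed, trial
index); per-trial streams are seeded `base + index`, and the compiled
inner loop (numba) makes a 220 000-step, 11 s trial run in ~0.3 s.
Batches consolidate per-class event matrices and export CSV event
tables plus a JSON provenance block (config hash, per-trial seeds);
re-running from the recorded seeds reproduces the batch bit-for-bit
(tested).  A mean-field mode (subunit master equation instead of
sampling, expected-value pools) backs the noise-free dose–response
characterizations and the comparison against an adaptive reference
integration of the identical equations (< 1% on peak IP₃).

## Parameters and calibration

The experimentally anchored values are fixed: the 50 μs step, the
300 nM detection threshold, the 22/15 μM sensor affinities, the 200 μM
/ 6.25 ms glutamate pulse, the 0.4–100 Hz sweep range and 11 s signal,
the 100 ms correlation window, and the Aβ transform magnitudes.  The
remaining rates and pool sizes are calibrated — once, as a set — to the
published characterization targets: resting Ca²⁺ below threshold with
a high-μM ER load; DHPG (100 μM, 2 s) evoking several μM-amplitude,
sub-second events per trial with kiss-and-run clustered in the window;
docked-pool recovery in 15–20 s; sub-20 nM mean deflection at 0.4 Hz vs
≥ 5 μM mean event amplitude at 100 Hz; and the fitted sensor
affinities.  Every calibrated key is listed under `_calibrated` in the
parameter file.  Test and acceptance runs use 15–100 trials per
condition (the published figures use 400–1000); Monte-Carlo tolerances
in the tests are sized for those counts.

## What the model does and does not capture

The compartment is well-mixed: no intra-process diffusion, no
multi-compartment morphology, no mitochondria or store-operated entry;
glutamate transporter kinetics are absorbed into the pulse decay
constant.  Two published observations are reproduced only partially or
not at all under this calibration, and the tests assert them honestly:

- The mobile-vesicle population stays roughly flat after a DHPG pulse
  rather than rising above baseline — continuous kiss-and-run
  recirculation through the mobile pool masks the transient surplus.
- At 100 Hz drive the PMCA condition does **not** suppress kiss-and-run
  release.  In this model the condition's doubled resting Ca²⁺ and
  elevated ER load increase Syt4 drive by more than full-fusion
  sequestration of mobile vesicles throttles docked-pool resupply; the
  corresponding one-sided test is expected to fail and documents this
  limit.  The companion effects — full fusion boosted, docked pool more
  deeply depleted, and the late-window Ca²⁺↔release correlation lower
  under combined pathology — do reproduce.
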