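# Methods

This note documents the models, the numerical choices and the open design
decisions behind `pulmovib`, and states precisely what the synthetic
generator does — and does not — establish.

## 1. Lumped-parameter circulation model (`hemo`)

### Topology and state

The pulmonary circulation is a closed loop of five storage compartments —
right ventricle (RV), proximal pulmonary artery (pap), distal pulmonary
artery (pad), pulmonary veins (pv) and a systemic reservoir — plus one
inertance branch:

```
reservoir --tricuspid--> RV --p-valve--> pap --R,L--> pad --R_pad--> pv --R_ret--> reservoir
```

The state vector is the five compartment volumes plus the pap→pad branch
flow.  Compliance nodes obey `dV/dt = Q_in − Q_out` with `P = V/C`; the
inertance branch obeys `dQ/dt = (ΔP − R·Q)/L`.  The resistive term on the
inertance branch is included deliberately: without it the branch is
lossless and the loop cannot settle into a physiological steady state.
Valves are piecewise-linear diodes (forward resistance 10⁻³, reverse
10³ mmHg·s/mL): numerically benign switching with < 1% reverse leakage
per cycle (tested).

The RV is a time-varying elastance chamber, `P = E(t)(V − V0)`, with the
double-Hill activation shape (parameters a₁ = 0.303, n₁ = 1.32,
a₂ = 0.508, n₂ = 21.9, normalized to peak 1) interpolating between
Emin = 0.045 and Emax = 0.8 mmHg/mL over a 1 s period.  The systemic side
is reduced to one large-compliance reservoir and one return resistance —
the package's focus is the pulmonary loop, and this minimal return path
only has to deliver a plausible preload.

### Parameter provenance

The original element values for this configuration were not available, so
the packaged set (`data/normal_circuit.yaml`) is a **reconstruction**:
standard pulmonary Windkessel magnitudes (total pulmonary resistance
≈ 0.19 mmHg·s/mL, arterial compliance ≈ 7 mL/mmHg split over two
segments), with Emax calibrated once so the steady state lands on the
study's stated normal operating point — RV systolic ≈ 23 mmHg with a
stroke volume of ~66 mL (the rig pumps 67 mL).  Every entry in the YAML
is flagged as reconstructed.  The calibration was done once, before the
test suite existed, and is not revisited.

### Integration and conventions

* Fixed-step classical RK4, dt = 0.1 ms, output decimated ×10 (1 kHz).
  RK4's stability region comfortably covers the stiffest time constant
  (forward-conducting valve into the arterial compliance, τ ≈ 1 ms).
* Steady state: relative cycle-over-cycle PASP change < 0.1% for three
  consecutive cycles.  The run stops there by default.
* Any node pressure exceeding 1000 mmHg in magnitude (or going
  non-finite) aborts with an error naming the node.
* Volume bookkeeping is exact by construction (each flow enters one
  compartment and leaves another); the tests bound total drift at
  0.1 mL / 10 s, and the observed drift is at round-off level (~10⁻¹¹ mL).
* Stenosis: the distal resistance follows `R(t) = 8ηL/(π r(t)⁴)` with
  `r(t) = r0(1+g_r t)^{−1/4}`, hence exactly `R(0)(1+g_r t)`; the
  schedule is re-evaluated every integrator step.
* Units: mmHg, mL, s inside the circuit.  The stand-alone physical
  formulas (Poiseuille resistance, the air-spring compliance of the
  bench rig's compliance chamber) evaluate in the caller's consistent
  unit system.  The air-spring formula has a removable 0/0 at
  `h_fluid = 0`; the implementation returns the physical limit 0.

## 2. Mock-loop emulator (`synth`)

The physical rig's acoustics are not modelled anywhere in the source
material — only its measured behaviour is.  The generator is therefore
phenomenological: waveform templates plus monotone response maps, all
driven by a dimensionless resistance setting `s` (0 = lowest discrete
state, 1 = highest), with coefficients fixed once in
`data/mcl_calibration.yaml`.

* **Pressure templates.**  Per cycle, the pulmonary-artery pressure rises
  from its diastolic baseline to the systolic peak along a half-cosine
  whose peak slope equals the target maximum rising rate, falls along a
  second half-cosine with the target falling rate, and holds.  The maps
  are affine in `s`: PASP = 28.5 + 58.01·s mmHg (so the six discrete
  states land on the rig's reported ladder 28.5 → 86.5 mmHg), rising rate
  0.14 → 0.19 and falling-rate magnitude 0.11 → 0.15 mmHg/ms across
  s ∈ [0, 1].  RV systolic pressure is PASP + 21.5 mmHg, reproducing the
  rig's 50 vs 28.5 mmHg baseline split; the mechanism behind that rig
  offset (a single-leaflet mechanical valve) is not modelled, only the
  offset itself.
* **Cycle timing.**  Period 1.03 s (inferred: ~581–584 cycles per
  10-minute run), servo duty 0.45, sampling 2000 Hz for all channels —
  enough margin for burst carriers ≤ 120 Hz.
* **Valve bursts.**  One exponentially damped sinusoid per valve per
  cycle, `A·e^{−λt}·sin(2πf_c t)`, λ = 60 s⁻¹.  The tricuspid burst
  follows the servo rising edge (closure at systole onset), the pulmonary
  burst the falling edge (diastole onset).  Response maps: delay
  decreasing in `s` (earlier closure under load), carrier frequency
  decreasing (90→60 Hz tricuspid, 80→50 Hz pulmonary — the rig's
  mechanical valves show this inverted frequency trend), amplitude affine
  in the transvalvular-pressure proxy (RV systolic for the tricuspid,
  PASP for the pulmonary).  Energy, spectral peak height and — through
  the fixed noise floor — both entropies then inherit their directions
  without separate tuning.
* **Noise.**  White Gaussian: 0.3 mmHg on pressures, 0.02 a.u. on sounds
  (SNR ≈ 20 dB at mid-range burst amplitude), plus a small per-cycle
  jitter of the setting whose SD grows from 0.003 to 0.0075, reproducing
  the rig's reported per-state PASP scatter (0.17 → ~0.45 mmHg).
* **Determinism.**  Every draw flows from `numpy.random.default_rng` on
  the explicit seed; dataset generators derive one child seed per
  recording.  Same seed → bit-identical output (tested).
* **Continuous sweeps.**  Triangular up-then-down schedules whose design
  endpoints sit 1–2 mmHg inside each run's reported PASP range, so jitter
  cannot push measured extremes outside the published envelope.

**What a green test establishes — and what it does not.**  The emulator
reproduces the rig's *calibrated* properties: pressure ladders and
ranges, trend directions, correlation signs, cycle counts and noise
scales.  Error magnitudes measured on it (e.g. regression MAEs) show the
pipeline can recover the pressure parameters under the stated noise
model; they do not certify performance on the physical rig (whose
measured MAEs arise from unmodelled hydraulic and acoustic variability),
still less on human subjects.

## 3. Signal processing (`sigproc`)

* **Pressure filter**: 4th-order Butterworth low-pass at 20 Hz, applied
  forward–backward (zero phase).  Only the filter family was given; the
  cutoff/order are this package's choice (pressure bandwidth < 10 Hz).
* **Sound denoising**: Daubechies-6, 5-level periodized DWT, universal
  threshold σ√(2 ln N) with soft shrinkage, σ from the MAD of the finest
  detail band.  No wavelet library is available in the target
  environment, so the transform is built in-package; the Daubechies
  filters are computed by spectral factorization at import and validated
  against the published db2/db3 coefficient tables in the tests.  The
  transform is orthonormal (even lengths), so thresholding can only
  remove energy.  Odd intermediate lengths are padded by sample
  repetition; one boundary sample is then only approximately
  reconstructed.
* **Segmentation**: half-amplitude threshold crossings of the servo
  pulse, 100 ms debounce; a cycle is rising-edge to rising-edge and must
  contain exactly one falling edge, else it is skipped with a log entry.
  The first and last generated cycles are lost at the boundaries.
* **Pressure parameters**: PASP is the maximum over the servo-high span.
  MRR/MFR use a Savitzky–Golay first derivative (50 ms cubic window) of
  the filtered trace — a raw first difference would bury the rate
  features (range ~0.05 mmHg/ms) under amplified noise, while the local
  polynomial keeps the bias on ≥150 ms upstrokes below 1% (tested).
* **Burst windows**: tricuspid search span = first 40% of systole from
  the rising edge; pulmonary = first 40% of diastole from the falling
  edge.  The window grows outward from the absolute-amplitude maximum,
  one sample at a time toward the side with the larger incremental
  energy (ties go left), until it holds 98% of the search-window energy.
  Growth is clipped at the search bounds (and at explicit servo-edge
  bounds if a caller passes a mis-specified window), with a flag; an
  essentially silent window returns a missing-burst flag and the cycle
  is dropped listwise downstream.

## 4. Features (`features`)

Eight features per burst, suffixed `_t`/`_p` per valve: Amp (max |x|),
Ener (Σx², sample-rate-proportional by choice, documented in units), MS
(time from the servo falling edge to the amplitude maximum, ms — one
convention for both valves, so the tricuspid value is referenced to the
previous cycle's falling edge), Time (window duration), f and Pow
(location/height of the Burg-AR power-spectrum main peak; AR order 12,
4096-point grid, coefficients from the Burg recursion in `statsmodels`),
SampEn and FuzzyEn (m = 2, tolerance 0.2·SD, fuzzy step n = 2, Chebyshev
distance, fuzzy templates mean-centred).  Both entropies are verified
against exhaustive brute-force template counting on short series, and
both are scale-invariant because the tolerance is SD-relative.  SampEn
returns NaN (undefined flag) when a template count is zero; FuzzyEn of a
constant series is 0 by convention.

## 5. Statistics (`stats`)

Kruskal–Wallis (tie-corrected, χ² approximation, via `scipy`) as the
omnibus test; the pairwise procedure behind the group-difference matrices
was not specified, so the package uses Dunn's rank-based z-tests with
Bonferroni correction at α = 0.05 — a logged substitution.  One caveat
discovered in testing: rank-based pairwise z-scores saturate with group
size, so adjacent groups need n ≳ 60 per group to reach corrected
significance regardless of separation; the 5-minute recordings (~290
cycles/state) are far above this.  Correlations are Pearson on per-cycle
rows pooled across runs, listwise-complete.

## 6. Regression (`regress`)

* **Feature network**: 7 inputs (MS_p, Ener_p, Amp_p, f_p, FuzzyEn_t,
  MS_t, f_t) → two hidden layers of 10 tanh units → 3 outputs.  Only the
  architecture was specified; training is this package's choice:
  per-fold standardization of inputs and targets, L-BFGS to (at most)
  2000 iterations, seed 42.  L-BFGS is deterministic given the seed and
  reaches the noise floor on this problem size in seconds.
* **Waveform model**: per cycle, both denoised sound channels over the
  full cycle are FFT-resampled to 256 samples (carriers stay well below
  the new Nyquist).  Architecture: two conv blocks (16/32 filters,
  kernel 7, stride 2, max-pool 2) → length-16 sequence → Bi-LSTM width
  32 per direction (final hidden states concatenated) → dense 3-output
  head.  Implemented directly in numpy with hand-derived backpropagation
  (no framework in the environment); the gradients are verified against
  central differences in the tests.  Training: Adam, lr 10⁻³, batch 64,
  40 epochs, MSE on standardized targets, seeded shuffling —
  bit-reproducible.
* **Validation**: leave-one-run-out; scalers and weights depend on the
  training folds only (leakage is tested by perturbing held-out data).
  The figure of merit is the pooled MAE over all held-out cycles.

On the default synthetic dataset the feature network and the waveform
model perform similarly (the emulator's bursts are much cleaner than the
rig's); the ordering of the two models is reported by the pipeline, not
asserted.

## 7. Known limitations

* The circuit parameters are reconstructions; only the calibrated
  operating point (RV systolic ≈ 23 mmHg, SV ≈ 66 mL) is anchored.
* The emulator's bursts are single damped sinusoids: no multi-modal
  valve ring-down, no sensor transfer function, no inter-channel
  crosstalk, no baseline wander.  Entropy features on such clean signals
  are driven mostly by the signal-to-noise ratio.
* The servo period (1.03 s) is inferred from cycle counts, not stated.
* MRR/MFR are estimator-dependent near their third significant digit;
  the Savitzky–Golay window is part of the packaged definition.
* The deep model is deliberately small (CPU budget); no hyperparameter
  search was performed for either model.
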