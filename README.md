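# pulmovib

Pulmonary-circulation simulation and heart-valve vibration-sound analysis
for noninvasive pulmonary artery pressure estimation.

## The problem

Pulmonary hypertension — a mean pulmonary arterial pressure (mPAP) above
25 mmHg — is usually confirmed by invasive right-heart catheterization.
The closure transients of the tricuspid and pulmonary valves, audible on
the chest wall as components of the heart sound, carry hemodynamic
information that could make continuous, noninvasive pressure monitoring
possible.  This package reproduces, as tested software, a bench-top study
of that idea:

1. **Circuit model** (`pulmovib.hemo`): a lumped-parameter (Windkessel)
   model of the pulmonary circulation — vessel segments as R/C/L
   elements, valves as diodes, the right ventricle as a time-varying
   elastance `P = E(t)·(V − V0)` — integrated with fixed-step RK4.
   Distal pulmonary artery stenosis (DPAS) is a shrinking vessel radius
   `r(t) = r0·(1 + g_r·t)^(−1/4)`, which by Poiseuille's law
   `R = 8ηL/(πr⁴)` makes the distal resistance grow exactly linearly.
2. **Mock-loop emulator** (`pulmovib.synth`): a seeded synthetic stand-in
   for the physical hydraulic rig.  It produces the five synchronously
   sampled channels (RV pressure, pulmonary-artery pressure, servo motor
   pulse, tricuspid and pulmonary vibration sounds) for six discrete
   resistance states and for continuous resistance sweeps, with valve
   closures as damped sinusoid bursts whose amplitude, timing and carrier
   frequency respond monotonically to the resistance setting.
3. **Signal processing** (`pulmovib.sigproc`): Butterworth low-pass for
   pressures, wavelet-threshold denoising for sounds, cycle segmentation
   from the servo pulse, per-cycle pressure parameters (PASP, maximum
   rising/falling rate), and 98%-energy burst-window extraction.
4. **Features** (`pulmovib.features`): per burst — amplitude, energy,
   timing from the servo falling edge (MS), duration, Burg-AR spectral
   main peak (f, Pow), sample entropy and fuzzy entropy.
5. **Statistics** (`pulmovib.stats`): Kruskal–Wallis omnibus plus
   Dunn–Bonferroni pairwise comparison across the six states; Pearson
   correlation of seven retained features with PASP/MRR/MFR.
6. **Regression** (`pulmovib.regress`): a 7-10-10-3 backward-propagation
   network on the features, and a CNN + bidirectional-LSTM model on the
   raw per-cycle waveforms, both validated leave-one-run-out.

`pulmovib.pipeline` orchestrates the two studies end to end.

## Worked example

```sh
python examples/01_circuit_normal_state.py
```

prints, from an actual run:

```
steady state reached: True
RV systolic pressure :  23.25 mmHg
PASP                 :  23.04 mmHg
mPAP                 :  18.56 mmHg
pulmonary hypertension (mPAP > 25): False
stroke volume        :   65.6 mL
RV stroke work       :   1128 mmHg*mL
```

— the healthy baseline: a right-ventricular systolic pressure of about
23 mmHg and an mPAP below the 25 mmHg hypertension threshold.  The other
examples walk through progressive stenosis, feature extraction from a
recording, the six-state group analysis and the continuous-sweep
regression; e.g. `examples/05_continuous_regression.py` ends with

```
  feature network : PASP 0.657 mmHg, MRR 0.0019, MFR 0.0017 mmHg/ms
  waveform model  : PASP 0.881 mmHg, MRR 0.0018, MFR 0.0016 mmHg/ms
```

(a 2-minute-per-run reduction of the full study): the pooled held-out
error of the pressure estimates, in the units of each parameter.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the headline quantities from scratch: the circuit model's
normal-state RV systolic pressure (t1), the feature-network
leave-one-run-out pooled MAEs for PASP/MRR/MFR on the default
five-run continuous-sweep dataset (t2–t4), and the waveform deep model's
pooled PASP MAE on the same data (t5), writing one JSON object with a
`value` and problem size `n` per target.  Runs in roughly ten minutes on
one CPU.

See `docs/methods.md` for the model details, parameter choices, what the
synthetic generator does and does not emulate, and known limitations.
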