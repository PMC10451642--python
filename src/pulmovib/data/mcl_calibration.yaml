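# Calibration of the synthetic mock-circulatory-loop emulator.
#
# The pressure maps are affine in the dimensionless resistance setting s
# (s = 0 is the lowest discrete resistance state, s = 1 the highest) and
# were fixed once against the rig's reported six-state pressure table and
# continuous-run ranges.  The burst response maps encode the measured
# directions: amplitude/energy increase, closure timing decreases and the
# spectral main peak moves down in frequency as distal resistance rises.
pressure:
  pasp_base: 28.5          # mmHg at s = 0
  pasp_span: 58.01         # mmHg per unit s (s = 1 -> 86.51)
  dia_base: 12.0           # diastolic baseline, mmHg at s = 0
  dia_span: 25.0
  rv_offset: 21.5          # RV systolic minus PASP (rig: 50 vs 28.5 mmHg)
  rv_dia: 2.0              # RV diastolic floor, mmHg
  mrr_base: 140.0          # max rising rate, mmHg/s at s = 0 (0.14 mmHg/ms)
  mrr_span: 50.0           # -> 0.19 mmHg/ms at s = 1
  mfr_base: 110.0          # max falling rate magnitude, mmHg/s at s = 0
  mfr_span: 40.0           # -> 0.15 mmHg/ms at s = 1
  transmission_delay_s: 0.02   # systole onset to PA upstroke
  setting_jitter_base: 0.003   # per-cycle SD of s at s = 0 (PASP SD ~0.17)
  setting_jitter_span: 0.0045  # grows with s (PASP SD ~0.44 at s = 1)

tricuspid:
  delay_base_ms: 30.0      # burst onset after servo rising edge at s = 0
  delay_span_ms: -12.0     # earlier closure as resistance rises
  freq_base_hz: 90.0       # burst carrier at s = 0
  freq_span_hz: -30.0
  amp_base: 0.10           # a.u.
  amp_per_mmhg: 0.008      # vs RV systolic pressure (transvalvular proxy)
  damping: 60.0            # s^-1

pulmonary:
  delay_base_ms: 45.0      # burst onset after servo falling edge at s = 0
  delay_span_ms: -20.0
  freq_base_hz: 80.0
  freq_span_hz: -30.0
  amp_base: 0.20
  amp_per_mmhg: 0.015      # vs PASP (diastolic PA-RV gradient proxy)
  damping: 60.0

# discrete resistance states: target mean PASP per state, mmHg
six_state_pasp: [28.50, 36.01, 47.85, 59.84, 69.72, 86.51]

# continuous sweep runs: design PASP range (mmHg) per 10-min run.  The
# schedule endpoints sit ~1-2 mmHg inside the run's observed range so the
# per-cycle jitter cannot push measured extremes outside it.
continuous_pasp_ranges:
  - [39.1, 92.5]
  - [39.8, 87.3]
  - [39.1, 89.2]
  - [50.3, 83.7]
  - [50.4, 79.8]
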