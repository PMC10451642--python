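# Normal-state pulmonary circulation parameter set (mmHg, mL, s).
#
# NOTE: these element values are a reconstruction from standard
# lumped-parameter pulmonary-circulation values, calibrated once so that
# the steady-state right-ventricular systolic pressure is ~23 mmHg with a
# physiological stroke volume; the original source values were not
# available.  reconstruction flags mark every calibrated entry.
reconstructed: true

rv:
  Emin: 0.045      # diastolic elastance, mmHg/mL (reconstructed)
  Emax: 0.8        # end-systolic elastance, mmHg/mL (calibrated to RVSP ~23)
  V0: 10.0         # unstressed volume, mL
  period: 1.0      # cardiac period, s

segments:
  - name: pap      # proximal pulmonary artery
    R: 0.03        # mmHg·s/mL
    C: 3.0         # mL/mmHg
    L: 0.0017      # mmHg·s²/mL
  - name: pad      # distal pulmonary artery (stenosis target)
    R: 0.16
    C: 4.0
    L: 0.0
  - name: pv       # pulmonary veins
    R: 0.0         # lumped into the return resistance
    C: 15.0
    L: 0.0

valves:
  - name: p-valve
    R_forward: 1.0e-3
    R_reverse: 1.0e+3
  - name: tricuspid
    R_forward: 1.0e-3
    R_reverse: 1.0e+3

reservoir:          # minimal systemic return path (left heart + veins lumped)
  C: 150.0          # mL/mmHg
  R_ret: 0.03       # pv -> reservoir, mmHg·s/mL

init:               # initial state (volumes mL, flow mL/s)
  V_rv: 90.0
  V_pap: 45.0       # ~15 mmHg
  V_pad: 50.0       # ~12.5 mmHg
  V_pv: 120.0       # ~8 mmHg
  V_res: 600.0      # ~4 mmHg
  Q_pp: 0.0
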