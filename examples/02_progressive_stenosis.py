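"""Distal pulmonary artery stenosis (DPAS) on the circuit model.

The distal vessel radius shrinks as r(t) = r0 (1 + gr t)^(-1/4), so by
Poiseuille's law the distal resistance grows linearly in time.  The right
ventricle must generate progressively more pressure to maintain output —
the hypertensive trajectory the bench rig reproduces hydraulically.
"""

from pulmovib import hemo

model = hemo.normal_model()
sched = hemo.StenosisSchedule.for_resistance(model.pad.R, gr=0.15)

print(f"distal resistance: R(0) = {sched.resistance_at(0):.3f}, "
      f"R(20 s) = {sched.resistance_at(20.0):.3f} mmHg*s/mL "
      f"(exactly {1 + 0.15 * 20:.0f}x)")

result = hemo.simulate(model, n_cycles=25, stenosis=sched,
                       stop_at_steady=False)
summary = hemo.summarize_pressures(result, steady_only=False)

print("cycle   RV peak [mmHg]   PASP [mmHg]")
for k in range(0, 25, 4):
    print(f"{k:5d}   {summary['per_cycle']['RV_systolic'][k]:10.2f}"
          f"   {summary['per_cycle']['PASP'][k]:10.2f}")

# Both pressures climb monotonically as the stenosis tightens: the
# per-cycle peak traces the widening pressure-volume loops of a right
# ventricle working against growing afterload.
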