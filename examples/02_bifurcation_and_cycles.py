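"""Nutrient response: the excitable-to-limit-cycle bifurcation in a0.

a0 is the basal, nutrient-dependent production of the G1/S activator x.
Below a critical value the system is excitable (a stable G1 state waits
for a trigger); above it the G1 state merges with the Start saddle and
the cell cycles continuously.
"""

import cyclescape as cs

params = cs.baseline_params()
a0c = cs.locate_bifurcation_a0(params, (0.001, 0.01), tolerance=1e-6)
print(f"critical nutrient parameter a0* = {a0c:.4g}")
print("(stable G1 exists below this value; the model's division switch)")

for a0 in (0.001, 0.01):
    regime = cs.classify_regime(params.with_updates(a0=a0))
    print(f"a0 = {a0}: regime = {regime}")

cyc = cs.detect_limit_cycle(params.with_updates(a0=0.01))
print(f"\nrich-nutrient limit cycle period: {cyc.period:.1f} time units")
print("(one autonomous division cycle when nutrients keep a0 above a0*)")
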