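"""Measure the calibrated model's passive constants with its own protocols.

Builds the calibrated surrogate thalamocortical cell and measures input
resistance (-10 pA, 100 ms pulse), membrane time constant (slowest term of
a double-exponential fit after a -1 nA, 0.5 ms pulse), capacitance
(tau/Rin) and resting potential.  The printed values should sit close to
the model's targets: 218.2 MOhm, 19.1 ms, 87.4 pF and -77.3 mV.
"""

from vmtc import build_cell, measure_passive_properties

cell = build_cell()
props = measure_passive_properties(cell)

print(f"compartments: {cell.n_comp}")
print(f"input resistance : {props['Rin']:8.1f} MOhm")
print(f"time constant    : {props['tau']:8.2f} ms")
print(f"capacitance      : {props['C']:8.2f} pF")
print(f"resting potential: {props['Vrest']:8.2f} mV")
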