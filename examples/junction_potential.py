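"""Liquid junction potential of the recording configuration.

Evaluates the stationary Henderson equation for the K-gluconate pipette
solution against the recording ACSF, using the bundled limiting-mobility
table.  The reported value is bath-minus-pipette; it is the correction
that would be subtracted from measured voltages (the reference analysis
reports uncorrected voltages, as does this package).
"""

from vmtc import junction_potential
from vmtc.features import ACSF_SOLUTION, PIPETTE_SOLUTION

ljp = junction_potential()
print("pipette (mM):", PIPETTE_SOLUTION)
print("bath    (mM):", ACSF_SOLUTION)
print(f"liquid junction potential: {ljp:.2f} mV (bath minus pipette)")
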