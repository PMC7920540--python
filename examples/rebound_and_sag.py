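"""Rebound bursting and sag under M-current block and IH scaling.

Rebound: -100 pA steps of 200/500/2000 ms from a ~-71 mV hold; the
post-inhibitory low-threshold calcium burst grows with step duration and
with full M-current block.  Sag: 2 s steps from rest (-50 to -200 pA);
the sag percentage 100*(1 - Vss/Vpeak) grows monotonically with current,
is raised slightly by M-current block and strongly by doubling or
tripling IH.
"""

from vmtc import apply_pharmacology, build_cell, rebound_metrics, sag_percent
from vmtc.protocols import run_rebound, run_sag

cell = build_cell()

print("rebound spike counts (-100 pA steps, hold -71 mV)")
print("condition   200 ms  500 ms  2000 ms")
for name, scales in (("control", {}), ("KM 50%", {"KM": 0.5}), ("KM 0%", {"KM": 0.0})):
    traces = run_rebound(apply_pharmacology(cell, scales))
    counts = [rebound_metrics(t)["rebound_spike_count"] for t in traces]
    print(f"{name:10s} {counts[0]:6d} {counts[1]:7d} {counts[2]:8d}")

print()
print("sag percentage (2 s steps from rest)")
print("condition      -50 pA  -100 pA  -150 pA  -200 pA")
for name, scales in (
    ("control", {}),
    ("KM 0%", {"KM": 0.0}),
    ("IH x2", {"IH": 2.0}),
    ("IH x3", {"IH": 3.0}),
    ("KM 0% IH x2", {"KM": 0.0, "IH": 2.0}),
):
    traces = run_sag(apply_pharmacology(cell, scales))
    sags = [sag_percent(t).sag_percent for t in traces]
    print(f"{name:13s}" + "".join(f" {s:8.1f}" for s in sags))
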