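"""Theta-phase readout of the somatic state, and why it needs slow recovery.

A spike riding a 5.2-Hz membrane oscillation evokes phase-dependent
calcium influx: distal dendrites report the phase strongly (through the
peak-amplitude effect), proximal ones weakly. The paired-pulse scan shows
the slow recovery from inactivation that low-pass filters the proximal
mechanism.
"""

import numpy as np

import bapflux as bf
from bapflux.experiments import recovery_scan, theta_scan

res = theta_scan(phases_deg=np.arange(0.0, 360.0, 45.0),
                 distances_um=(40.0, 150.0))
print("calcium charge vs theta phase (% change relative to rest):")
print("phase (deg):", "  ".join(f"{p:6.0f}" for p in res.axes["phase_deg"]))
for row, label in zip(res.values, ("proximal", "distal")):
    print(f"{label:>9s}:  ", "  ".join(f"{v:+6.1f}" for v in row))

rec = recovery_scan("HI_only", interpulse_ms=[25, 50, 100, 200, 400, 800, 1600])
print()
print("recovery from inactivation (second/first pulse peak ratio):")
for gap, ratio in zip(rec.axes["interpulse_ms"], rec.values):
    print(f"  {gap:6.0f} ms  ->  {ratio:.3f}")
print(f"fitted recovery tau: {rec.provenance['recovery_tau_ms']:.0f} ms")

print()
print("Distal influx is largest at depolarized phases (40-160 deg) and "
      "smallest in the trough (219-339 deg); the ~400-ms recovery means the "
      "availability of the inactivating channel cannot follow single theta "
      "cycles, keeping the proximal modulation shallow.")
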