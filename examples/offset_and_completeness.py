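"""Why distal dendrites read the bAP peak and proximal ones do not.

Shifts proximal (24 um) and distal (150 um) spike commands in 2-mV steps
and, separately, extends them with a pre-peak voltage plateau: the large
proximal spike already activates nearly all available HVA channels, so
neither manipulation changes its calcium charge much, while the small
distal spike is acutely sensitive to both.
"""

import bapflux as bf
from bapflux.experiments import completeness_scan, offset_scan

prox = bf.generate_bap(24.0, "depolarized")
dist = bf.generate_bap(150.0, "depolarized")

res = offset_scan([prox, dist], offsets_mV=[6, 0, -6, -12, -18, -24, -30])
print("charge vs voltage offset (% of unshifted):")
print("offset (mV):", "  ".join(f"{o:+6.0f}" for o in res.axes["offset_mV"]))
for row, label in zip(res.values, ("proximal", "distal")):
    print(f"{label:>8s}:   ", "  ".join(f"{v:6.1f}" for v in row))

print()
print("charge vs pre-peak plateau extension (% of unextended):")
exts = [0.0, 0.75, 2.0, 3.5, 5.0]
for cmd, label in ((prox, "proximal"), (dist, "distal")):
    vals = completeness_scan(cmd, exts).values
    print(f"{label:>8s}:   ", "  ".join(f"{v:6.1f}" for v in vals))

print()
print("Distal charge collapses under negative offsets and grows strongly "
      "with plateau extensions (submaximal activation); proximal charge "
      "barely moves (activation already near-complete).")
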