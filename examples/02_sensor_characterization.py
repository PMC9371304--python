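"""Characterize the two release sensors at clamped Ca2+ levels.

Starting from fully unbound sensors and full vesicle pools, the
expected kiss-and-run (Syt4) and full-fusion (Syt7) release rates are
integrated deterministically for a ladder of steady-state Ca2+
concentrations; the peak rate per level is then fitted with a Hill
function.  The fitted dissociation constants should land near the
sensors' literature affinities: ~22 uM for the fast single-site Syt4
and ~15 uM for the slow five-site Syt7.
"""

import numpy as np

import gliosim as g
from gliosim.release import characterize_clamped

_, sensors, pools = g.default_parameters()
ca = np.geomspace(1.0, 200.0, 10)
out = characterize_clamped(sensors, ca, pools, duration=3.0)

fit4 = g.fit_hill(ca, out["kr_peak"])
fit7 = g.fit_hill(ca, out["ff_peak"])

print("Ca (uM)   Syt4 peak (1/s)  ttp (ms)   Syt7 peak (1/s)  ttp (ms)")
for i, c in enumerate(ca):
    print(f"{c:7.1f}   {out['kr_peak'][i]:12.1f}  {1e3 * out['kr_time_to_peak'][i]:8.1f}"
          f"   {out['ff_peak'][i]:12.1f}  {1e3 * out['ff_time_to_peak'][i]:8.1f}")
print()
print(f"Syt4 Hill fit: kd = {fit4.kd:.1f} uM, slope n = {fit4.n:.2f}")
print(f"Syt7 Hill fit: kd = {fit7.kd:.1f} uM, slope n = {fit7.n:.2f}")
print()
print("Syt4 peaks within milliseconds (time-to-peak falls with Ca2+); "
      "Syt7 needs hundreds of milliseconds and reaches far lower rates — "
      "the kinetic separation behind synchronous kiss-and-run vs "
      "asynchronous full fusion.")
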