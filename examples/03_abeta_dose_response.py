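"""Verify the amyloid-beta parameter transforms through dose-response fits.

The Abeta-mGluR condition halves the receptor's half-activation and
doubles its maximal IP3 production; the Abeta-PMCA condition scales the
pump's backward rate until its fitted Ca2+ affinity halves.  Both are
verified here the same way they are reported: by Hill fits of the
noise-free DHPG -> peak-IP3 curve and of the steady-state PMCA flux
curve, under control and transformed parameters.
"""

import numpy as np

import gliosim as g

mp, _, _ = g.default_parameters()

doses = np.array([2, 5, 10, 20, 40, 80, 160, 320, 640], float)
fit_c = g.fit_hill(*g.ip3_dose_response(mp, doses))
ab_m = g.apply_condition(mp, g.ConditionSpec(abeta_mglur=True))
fit_m = g.fit_hill(*g.ip3_dose_response(ab_m, doses))
print("DHPG -> peak IP3 dose-response:")
print(f"  control    : kd = {fit_c.kd:5.1f} uM, Vmax = {fit_c.vmax:.3f} uM")
print(f"  Abeta-mGluR: kd = {fit_m.kd:5.1f} uM, Vmax = {fit_m.vmax:.3f} uM")
print(f"  half-activation reduced by {100 * (1 - fit_m.kd / fit_c.kd):.1f}%, "
      f"maximal response x{fit_m.vmax / fit_c.vmax:.2f}")

ca = np.geomspace(0.01, 10.0, 25)
pfit_c = g.fit_hill(*g.pmca_dose_response(mp, ca))
ab_p = g.apply_condition(mp, g.ConditionSpec(abeta_pmca=True))
pfit_p = g.fit_hill(*g.pmca_dose_response(ab_p, ca))
print()
print("steady-state PMCA flux:")
print(f"  control   : half-saturation = {pfit_c.kd:.3f} uM")
print(f"  Abeta-PMCA: half-saturation = {pfit_p.kd:.3f} uM "
      f"(affinity reduced by {100 * (1 - pfit_c.kd / pfit_p.kd):.1f}%)")

r_c = g.resting_state(mp)
r_p = g.resting_state(ab_p)
print()
print("resting levels (control -> Abeta-PMCA):")
print(f"  cytosolic Ca2+: {1e3 * r_c.ca_cyt:.0f} -> {1e3 * r_p.ca_cyt:.0f} nM")
print(f"  ER Ca2+       : {r_c.ca_er:.0f} -> {r_p.ca_er:.0f} uM")
print()
print("The weakened pump shifts the membrane flux balance upward, raising "
      "both resting cytosolic and ER Ca2+ — the modeled route to "
      "Abeta-associated Ca2+ overload.")
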