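"""Fit the facilitated-dissociation model to the packaged study tables.

The reduced model R = 1 + EFD*[A]/(K_d*(K_d,m+[A])) is fitted jointly over
the six albumin-bound OAT3 substrates (shared EFD and K_d,m), then the
OAT1 panel is fitted with K_d,m frozen at the OAT3 estimate — the OAT1
panel alone (three substrates) cannot identify both parameters.  The full
model (per-substrate V_b,max) is fitted the same way.
"""

from renalivive import datasets, pipeline
from renalivive.domain import OAT1, OAT3

fd = pipeline.table_fd_fits()

r3 = fd["reduced_oat3"]
print(f"OAT3 reduced model: EFD = {r3.efd:.0f} uM, K_d,m = {r3.kdm:.0f} uM "
      f"({r3.n_points} R values, {len(datasets.BOUND_SUBSTRATES)} substrates)")
r1 = fd["reduced_oat1"]
print(f"OAT1 reduced model: EFD = {r1.efd:.0f} uM "
      f"(K_d,m frozen at the OAT3 value)")
f3 = fd["full_oat3"]
print(f"OAT3 full model:    K_d,m = {f3.kdm:.0f} uM; per-substrate V_b,max:")
for sub, vb in f3.vbmax.items():
    print(f"    {sub:20s} {vb:10.1f} pmol/min/mg")

print("\nEFD measures how much extra unbound drug the albumin-membrane"
      "\ninteraction supplies per unit of binding; the larger OAT1 EFD"
      "\nmatches the stronger albumin effect seen on that transporter."
      "\nK_d,m ~ 500 uM approaches the physiological albumin concentration.")
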