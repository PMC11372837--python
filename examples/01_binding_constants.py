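"""Fit albumin-ligand dissociation constants from equilibrium-dialysis data.

Loads the packaged fraction-unbound table (eight OAT1/3 substrates at 1%
and 4% HSA) and refits K_d for each.  Small K_d = tight albumin binding;
the two clinical probe substrates barely bind and are flagged as
effectively unbound.
"""

from renalivive import datasets
from renalivive.binding import BindingMeasurement, fit_kd
from renalivive.domain import AlbuminCondition

frame = datasets.binding_measurement_frame()
print(f"{'substrate':28s} {'K_d (uM)':>12s}  note")
for sub, grp in frame.groupby("substrate"):
    measurements = [
        BindingMeasurement(sub, AlbuminCondition.hsa(r["albumin_g_per_dl"]),
                           [r["fu_mean"]])
        for _, r in grp.iterrows()
    ]
    fit = fit_kd(measurements, weighting="relative")
    note = "effectively unbound" if fit.unbound_flag else ""
    print(f"{sub:28s} {fit.kd:12.1f}  {note}")

print("\nK_d is the albumin concentration at which half the drug is bound;"
      "\nsubstrates with K_d far above the 4% HSA level (~600 uM) see no"
      "\nalbumin-mediated uptake effect.")
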