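"""Bottom-up prediction of renal clearance from in vitro uptake data.

Derives the REF and RAF scalers from the packaged abundance/probe table,
then predicts intrinsic secretion clearance, plasma secretion clearance
and total renal clearance for the substrate panel, comparing the
albumin-free (control) and 4% HSA conditions under REF scaling.
"""

from renalivive import pipeline

scalers = pipeline.load_scalers()
for t, s in scalers.items():
    print(f"{t}: REF = {s.ref:.1f}, RAF = {s.raf:.1f} "
          f"(probe: {s.reference_probe})")

print(f"\n{'substrate':26s} {'CL_r ctrl':>10s} {'CL_r 4%':>10s}   (mL/min, REF)")
ctrl = pipeline.predict_panel(mode="REF", hsa_level="control")
hsa4 = pipeline.predict_panel(mode="REF", hsa_level="hsa_4pct")
for sub in ctrl:
    print(f"{sub:26s} {ctrl[sub].cl_r:10.1f} {hsa4[sub].cl_r:10.1f}")

olm = hsa4["olmesartan"]
print(f"\nolmesartan at 4% HSA: CL_int,sec = {olm.clint_sec:.0f} mL/min, "
      f"CL_sec = {olm.cl_sec:.1f} mL/min, "
      f"OAT1 share = {olm.fraction_by_transporter.get('OAT1', 0):.0%}")

print("\nFor highly bound substrates the 4% HSA measurements give much"
      "\nlarger scaled clearances than the albumin-free control — the"
      "\ncorrection that repairs the classic underprediction of renal"
      "\nsecretion for this class of drugs.")
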