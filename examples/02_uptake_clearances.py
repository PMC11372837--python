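"""From raw uptake time courses to active clearances and albumin-effect
ratios.

Simulates a small noiseless experiment (so the printed numbers can be
checked against the generating truth), then runs the standard processing:
slope of amount vs time -> unbound intrinsic clearance -> subtraction of
the probenecid (passive) clearance -> fold-change ratio R per HSA level.
"""

from renalivive import pipeline, simulate

truth = simulate.paper_like_truth(seed=11, n_substrates=3,
                                  uptake_cv=0.0, fu_noise_sd=0.0)
panel = simulate.generate_panel(truth)
clearances, ratios = pipeline.process_timecourses(panel.timecourses)

for sub in truth.substrates:
    cs = clearances[(sub, "OAT3")]
    mean_ctrl, _ = cs.mean_sd("control")
    print(f"{sub}: active CL_int,u (control) = {mean_ctrl:.3f} uL/min/mg "
          f"(truth {truth.clint_active_free[sub]:.3f})")
    for cond, rr in sorted(ratios[(sub, 'OAT3')].items()):
        print(f"    R at {cond:9s} = {rr.r_mean:6.2f}")

print("\nR > 1 means albumin increased the unbound active uptake clearance"
      "\nbeyond the free-drug expectation; it grows with the albumin level"
      "\nand with the tightness of drug-albumin binding.")
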