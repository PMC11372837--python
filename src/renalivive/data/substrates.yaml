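# Substrate panel: transporter specificity established by probenecid
# inhibition and cross-line uptake screens; fraction unbound in plasma
# (fu_p) where reported.  Weakly bound probes double as negative controls
# for the albumin-mediated uptake effect.
substrates:
  olmesartan:        {transporters: [OAT1, OAT3], fu_p: 0.0026}
  bumetanide:        {transporters: [OAT1, OAT3]}
  4-pyridoxic acid:  {transporters: [OAT1, OAT3], fu_p: 0.092}
  furosemide:        {transporters: [OAT3]}
  rivaroxaban:       {transporters: [OAT3]}
  rosuvastatin:      {transporters: [OAT3]}
  adefovir:          {transporters: [OAT1], reference_probe_for: OAT1}
  oseltamivir carboxylate: {transporters: [OAT3], reference_probe_for: OAT3}
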