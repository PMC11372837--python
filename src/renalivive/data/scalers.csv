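transporter,abundance_invivo_mean,abundance_invivo_sd,abundance_invitro_mean,abundance_invitro_sd,clint_invivo_ref,clint_invitro_ref_mean,clint_invitro_ref_sd,reference_probe
OAT1,10.2,10.1,1.28,0.32,35.2,17.6,4.4,adefovir
OAT3,9.6,9.8,0.30,0.14,36.2,0.23,0.08,oseltamivir carboxylate
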