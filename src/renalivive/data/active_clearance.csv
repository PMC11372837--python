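transporter,substrate,clint_control_mean,clint_control_sd,clint_1pct_mean,clint_1pct_sd,clint_4pct_mean,clint_4pct_sd,r_1pct_mean,r_1pct_sd,r_4pct_mean,r_4pct_sd
OAT1,olmesartan,0.34,0.13,6.45,3.52,38.9,6.0,17.9,4.0,122,42
OAT1,bumetanide,0.32,0.08,4.26,0.70,12.9,3.31,13.7,1.4,43.2,15.5
OAT1,4-pyridoxic acid,0.84,0.07,1.59,0.41,2.90,0.16,1.92,0.65,3.46,0.47
OAT1,adefovir,17.6,4.4,23.7,3.4,18.3,3.3,1.41,0.43,1.05,0.07
OAT3,olmesartan,0.65,0.04,6.74,1.00,18.3,1.8,10.5,2.3,28.1,3.0
OAT3,bumetanide,1.00,0.40,5.68,0.54,13.0,6.9,6.4,2.8,12.8,2.9
OAT3,4-pyridoxic acid,0.16,0.03,0.41,0.13,0.59,0.13,2.64,1.12,3.85,1.30
OAT3,furosemide,0.56,0.16,3.65,1.15,11.1,0.7,6.52,0.90,21.1,7.7
OAT3,rivaroxaban,0.65,0.12,4.03,0.95,6.47,1.13,6.44,2.61,10.0,2.2
OAT3,rosuvastatin,0.66,0.33,1.31,0.54,1.71,0.84,2.12,0.58,2.68,0.62
OAT3,oseltamivir carboxylate,0.23,0.08,0.22,0.04,0.20,0.05,1.04,0.24,0.95,0.18
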