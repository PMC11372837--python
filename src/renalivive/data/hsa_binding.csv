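substrate,fu_1pct_mean,fu_1pct_sd,fu_4pct_mean,fu_4pct_sd,kd_um,kd_um_sd
olmesartan,0.011,0.001,0.0020,0.0002,1.43,0.10
bumetanide,0.141,0.012,0.029,0.003,21.1,1.4
furosemide,0.162,0.030,0.038,0.002,26.1,1.6
rivaroxaban,0.217,0.006,0.096,0.007,55.0,4.3
4-pyridoxic acid,0.298,0.005,0.079,0.006,56.4,2.5
rosuvastatin,0.435,0.041,0.180,0.009,126.7,5.6
oseltamivir carboxylate,0.973,0.039,0.983,0.018,26300,18900
adefovir,0.999,0.019,0.977,0.062,27100,35200
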