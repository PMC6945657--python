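energy_fwhm_mev,avg_uncertainty_pct,rate_3_3,rate_2_2,rate_1_1
0.120,7.9,100.0,92.6,53.4
0.140,7.9,100.0,99.4,68.3
0.150,7.9,100.0,99.4,70.8
0.160,7.9,100.0,98.1,65.8
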