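energy_fwhm_mev,avg_uncertainty_pct,rate_3_3,rate_2_2,rate_1_1
0.100,5.9,100.0,96.9,72.1
0.120,5.9,100.0,98.8,78.3
0.140,6.0,100.0,98.8,80.1
0.150,5.9,100.0,98.1,75.2
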