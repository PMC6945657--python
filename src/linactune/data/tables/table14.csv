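focal_spot_fwhm_cm,avg_uncertainty_pct,rate_3_3,rate_2_2,rate_1_1
0.10,5.9,100.0,97.5,71.4
0.12,5.9,100.0,100.0,73.9
0.13,5.9,99.4,91.3,66.5
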