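focal_spot_fwhm_cm,avg_uncertainty_pct,rate_3_3,rate_2_2,rate_1_1
0.10,7.9,100.0,98.8,67.7
0.12,7.9,100.0,100.0,68.9
0.14,7.9,100.0,99.4,72.1
0.15,7.9,100.0,100.0,78.9
0.16,7.9,100.0,93.8,75.2
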