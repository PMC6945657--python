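divergence_deg,avg_uncertainty_pct,rate_3_3,rate_2_2,rate_1_1
1,8.0,100.0,93.8,48.4
2,8.0,100.0,87.6,56.5
3,8.1,100.0,98.8,75.8
4,8.2,100.0,98.8,60.2
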