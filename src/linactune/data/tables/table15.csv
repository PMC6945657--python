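divergence_deg,avg_uncertainty_pct,rate_3_3,rate_2_2,rate_1_1
1,6.0,100.0,100.0,81.4
2,6.0,100.0,95.0,74.5
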