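n_histories_1e6,avg_uncertainty_pct,rate_3_3,rate_2_2,rate_1_1
5,12.8,99.4,73.6,29.0
10,9.4,99.4,75.2,30.0
25,6.1,100.0,100.0,77.1
65,3.8,100.0,99.7,84.2
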