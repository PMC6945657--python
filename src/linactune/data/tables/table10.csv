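n_histories_1e6,avg_uncertainty_pct,rate_3_3,rate_2_2,rate_1_1
5,12.4,99.4,85.1,62.1
10,9.1,98.8,85.1,54.0
25,5.9,100.0,100.0,74.5
65,3.7,100.0,90.7,55.9
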