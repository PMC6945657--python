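n_histories_1e6,avg_uncertainty_pct,rate_3_3,rate_2_2,rate_1_1
5,12.8,96.9,93.8,67.7
10,9.4,100.0,93.8,67.7
25,6.1,100.0,100.0,78.9
65,3.8,99.9,87.0,62.1
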