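n_histories_1e6,avg_uncertainty_pct,rate_3_3,rate_2_2,rate_1_1
2,36.4,91.2,57.5,17.5
5,18.0,97.4,74.0,24.7
10,12.1,100.0,88.0,38.0
25,7.9,100.0,99.7,74.7
100,4.1,100.0,100.0,84.1
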