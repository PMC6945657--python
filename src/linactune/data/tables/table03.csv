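n_histories_1e6,avg_uncertainty_pct,rate_3_3,rate_2_2,rate_1_1
2,36.4,100.0,96.9,59.6
5,18.0,100.0,93.2,54.7
10,12.1,100.0,96.9,58.4
25,7.9,99.4,81.4,47.8
100,4.1,99.4,95.7,75.2
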