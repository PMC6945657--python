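n_histories_1e6,avg_uncertainty_pct,rate_3_3,rate_2_2,rate_1_1
5,12.4,99.0,86.1,42.9
10,9.1,100.0,98.7,65.2
25,5.9,100.0,97.7,60.3
65,3.7,100.0,93.6,51.6
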