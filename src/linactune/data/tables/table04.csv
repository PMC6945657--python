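n_histories_1e6,avg_uncertainty_pct,rate_3_3,rate_2_2,rate_1_1
2,50.2,95.0,66.5,38.5
5,27.3,98.8,70.8,42.9
10,15.5,100.0,98.8,64.6
25,9.6,98.8,79.5,42.9
100,5.1,100.0,98.1,77.6
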