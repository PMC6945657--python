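n_histories_1e6,avg_uncertainty_pct,rate_3_3,rate_2_2,rate_1_1
2,50.2,100.0,91.2,47.1
5,27.3,90.6,56.2,19.2
10,15.5,75.0,31.8,11.4
25,9.6,90.3,54.2,14.6
100,5.1,99.4,72.4,18.5
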