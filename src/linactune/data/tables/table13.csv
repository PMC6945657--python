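energy_fwhm_mev,avg_uncertainty_pct,rate_d2p4,rate_d5p0,rate_d10p0,rate_d20p0,rate_d30p0
0.120,5.9,59.0,74.5,39.8,78.3,45.3
0.140,5.9,80.1,36.6,14.3,36.0,9.9
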