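gm_g,cc_g,ae_g,dpph_pct,dpph_sd,dpph_fpi,abts_pct,abts_sd,abts_fpi
5,10,15,77.20,1.42,0.4,83.70,2.73,0.4
5,15,10,76.80,2.22,0.4,90.511,0.61,0.4
10,5,15,74.91,1.65,0.4,91.25,0.94,0.4
10,15,5,80.33,1.29,0.5,92.20,0.35,0.5
10,10,10,76.23,1.14,0.4,91.89,0.48,0.4
15,5,10,75.62,1.34,0.4,91.04,0.99,0.4
15,10,5,77.20,1.10,0.4,88.96,1.29,0.4
30,0,0,69.68,2.48,,75.11,0.82,
0,30,0,74.35,1.78,,79.57,0.63,
0,0,30,30.74,1.03,,50.11,1.20,
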