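gm_g,cc_g,ae_g,water_pct,water_sd,ethanol_pct,ethanol_sd
5,10,15,53.47,8.14,98.86,1.12
5,15,10,26.30,6.36,96.57,1.62
10,5,15,52.31,4.75,75.14,1.71
10,15,5,26.88,8.55,94.29,1.44
10,10,10,64.74,4.86,98.29,0.93
15,5,10,63.01,6.36,93.43,1.71
15,10,5,54.62,7.46,97.14,1.95
30,0,0,15.90,5.20,95.43,2.16
0,30,0,4.62,2.75,96.86,0.57
0,0,30,17.44,3.34,76.00,1.44
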