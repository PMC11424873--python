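gm_g,cc_g,ae_g,inhibition_10,sd_10,inhibition_20,sd_20,inhibition_50,sd_50,ic50,ic50_sd
5,10,15,44.84,2.41,66.10,1.56,98.86,1.12,12.05,0.94
5,15,10,33.73,5.66,56.64,4.69,96.57,1.62,16.76,2.35
10,5,15,33.99,1.95,48.23,4.29,75.14,1.71,21.85,3.85
10,15,5,33.20,3.55,63.56,4.29,94.29,1.44,15.15,1.37
10,10,10,45.50,9.77,64.97,4.15,98.29,0.93,11.47,4.08
15,5,10,34.79,3.25,62.43,4.45,93.43,1.71,15.12,1.50
15,10,5,24.74,0.51,60.73,3.61,97.14,1.95,16.89,0.76
30,0,0,35.32,2.14,78.81,3.24,95.43,2.16,11.63,1.30
0,30,0,45.50,3.19,71.89,2.14,96.86,0.57,13.51,3.56
0,0,30,29.10,3.68,32.63,4.50,76.00,1.44,51.00,5.41
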