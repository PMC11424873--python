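label,gm_g,cc_g,ae_g,ic20_ug_ml,ic20_sd
GM,30,0,0,35.21,
CC,0,30,0,10.68,
AE,0,0,30,16.19,
5:10:15,5,10,15,35.93,23.29
10:10:10,10,10,10,27.43,8.59
10:15:5,10,15,5,147.04,
15:5:10,15,5,10,128.16,
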