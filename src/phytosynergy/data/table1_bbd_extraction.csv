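run,gm_g,cc_g,ae_g,yield_ethanol,yield_water,phenolic_ethanol,phenolic_water,flavonoid_ethanol,flavonoid_water
1,10,5,15,7.65,6.78,173.17,30.33,120.45,5.47
2,5,10,5,4.94,4.43,117.11,16.54,70.17,7.41
3,10,15,5,9.17,5.61,228.50,33.33,125.25,5.63
4,10,5,5,5.93,3.85,120.20,26.51,84.72,9.03
5,10,10,10,4.88,9.67,175.83,37.83,106.26,11.06
6,10,10,10,4.67,9.27,173.83,37.83,109.57,11.46
7,5,10,15,7.35,8.35,90.83,23.17,65.05,6.19
8,15,10,15,9.15,7.79,221.37,37.39,136.18,10.77
9,5,15,10,8.78,6.52,151.17,17.50,83.63,3.29
10,15,10,5,8.31,8.32,151.83,29.00,113.33,2.91
11,15,5,10,9.03,6.37,231.67,36.50,143.60,4.82
12,10,15,15,8.66,8.38,218.27,33.42,131.63,10.15
13,5,5,10,5.7,3.94,101.16,16.88,71.46,6.73
14,15,15,10,8.86,8.29,231.31,37.05,134.90,10.45
15,10,10,10,5.02,10.07,161.83,37.17,110.45,11.19
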