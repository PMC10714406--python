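energy_kev,mu_per_mm
15,0.075951426
20,0.043759427
30,0.024260717
40,0.019246889
50,0.017180255
60,0.016028674
80,0.014668485
100,0.013776397
150,0.012250525
200,0.011178165
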