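energy_kev,mu_per_mm
15,0.081245201
20,0.045820792
30,0.027720202
40,0.022921151
50,0.020851547
60,0.019631239
80,0.018108609
100,0.017059161
150,0.015203261
200,0.01387974
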