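energy_kev,mu_per_mm
15,0.079438237
20,0.045716505
30,0.024593244
40,0.019206093
50,0.017014742
60,0.015814348
80,0.014423486
100,0.013528266
150,0.012017081
200,0.01096188
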