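energy_kev,mu_per_mm
15,0.31325901
20,0.15586934
30,0.061670688
40,0.038172173
50,0.029426436
60,0.025284986
80,0.021494159
100,0.0196046
150,0.017097432
200,0.015559995
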