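energy_kev,mu_per_mm
15,0.22734119
20,0.11841679
30,0.049613409
40,0.03249953
50,0.026057486
60,0.022934497
80,0.019927653
100,0.018336684
150,0.016075471
200,0.014631921
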