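energy_kev,mu_per_mm
15,0.18438228
20,0.099690511
30,0.043584769
40,0.029663208
50,0.024373012
60,0.021759252
80,0.0191444
100,0.017702725
150,0.01556449
200,0.014167885
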