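energy_kev,mu_per_mm
15,0.073528853
20,0.042399043
30,0.023989904
40,0.019227733
50,0.017246097
60,0.0161286
80,0.014791332
100,0.013903363
150,0.012371658
200,0.011290804
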