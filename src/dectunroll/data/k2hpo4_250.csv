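energy_kev,mu_per_mm
15,0.35621793
20,0.17459561
30,0.067699328
40,0.041008494
50,0.031110911
60,0.026460231
80,0.022277412
100,0.020238558
150,0.017608412
200,0.016024032
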