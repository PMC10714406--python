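energy_kev,mu_per_mm
15,0.14142337
20,0.080964236
30,0.037556129
40,0.026826887
50,0.022688537
60,0.020584007
80,0.018361147
100,0.017068767
150,0.01505351
200,0.013703848
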