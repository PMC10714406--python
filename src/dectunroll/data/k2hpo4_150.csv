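energy_kev,mu_per_mm
15,0.2703001
20,0.13714306
30,0.055642048
40,0.035335851
50,0.027741961
60,0.024109741
80,0.020710906
100,0.018970642
150,0.016586451
200,0.015095958
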