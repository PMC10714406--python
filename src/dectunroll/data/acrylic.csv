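energy_kev,mu_per_mm
15,0.11997351
20,0.067989735
30,0.036078908
40,0.027961666
50,0.024676917
60,0.022887944
80,0.020834428
100,0.019525387
150,0.017330109
200,0.015803603
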