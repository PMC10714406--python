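energy_kev,mu_per_mm
15,0.51243847
20,0.23620762
30,0.085999873
40,0.048389165
50,0.034706614
60,0.028355396
80,0.023103833
100,0.020633545
150,0.017715658
200,0.01613657
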