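column_index,dose_modulation_factor,let_kev_um
1,0.8415,1.2269
2,0.9131,1.4134
3,1.0009,2.2267
4,1.0004,2.3710
5,1.0006,2.5418
6,0.9997,2.7281
7,1.0002,3.0143
8,0.9992,3.4235
9,1.0007,4.0951
10,0.9978,5.6344
11,0.2549,14.1959
12,7.94e-4,4.15e-6
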