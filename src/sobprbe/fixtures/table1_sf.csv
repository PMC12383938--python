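column_index,cell_line,dose_label,sf_mean,sf_sd
1,A549,SF2,0.7272,0.3517
2,A549,SF2,0.9787,0.4724
3,A549,SF2,0.5000,0.2757
4,A549,SF2,0.7045,0.3489
5,A549,SF2,0.6809,0.3975
6,A549,SF2,0.4043,0.2461
7,A549,SF2,0.4792,0.2645
8,A549,SF2,0.6000,0.4695
9,A549,SF2,0.2500,0.1792
10,A549,SF2,0.3913,0.2731
11,A549,SF2,0.5227,0.3763
12,A549,SF2,0.7843,0.3894
1,A549,SF4,0.6818,0.4573
2,A549,SF4,0.6064,0.3943
3,A549,SF4,0.2963,0.2726
4,A549,SF4,0.3977,0.4232
5,A549,SF4,0.2128,0.1712
6,A549,SF4,0.3723,0.5227
7,A549,SF4,0.2917,0.2893
8,A549,SF4,0.3400,0.3974
9,A549,SF4,0.2115,0.1956
10,A549,SF4,0.2391,0.2507
11,A549,SF4,0.3750,0.3141
12,A549,SF4,0.9804,0.4558
1,Panc-1,SF2,0.7917,0.2077
2,Panc-1,SF2,0.7907,0.2886
3,Panc-1,SF2,0.7027,0.2694
4,Panc-1,SF2,0.6429,0.2919
5,Panc-1,SF2,0.7105,0.2190
6,Panc-1,SF2,1.1111,0.3440
7,Panc-1,SF2,1.0323,0.4057
8,Panc-1,SF2,0.7317,0.1987
9,Panc-1,SF2,0.6111,0.2150
10,Panc-1,SF2,0.9667,0.3012
11,Panc-1,SF2,0.7429,0.3620
12,Panc-1,SF2,1.1860,0.5081
1,Panc-1,SF4,0.4167,0.1460
2,Panc-1,SF4,0.5000,0.1990
3,Panc-1,SF4,0.2162,0.2754
4,Panc-1,SF4,0.1905,0.2215
5,Panc-1,SF4,0.0789,0.1878
6,Panc-1,SF4,0.2222,0.2257
7,Panc-1,SF4,0.1290,0.2489
8,Panc-1,SF4,0.1463,0.1807
9,Panc-1,SF4,0.0833,0.1177
10,Panc-1,SF4,0.0667,0.1331
11,Panc-1,SF4,0.5143,0.2590
12,Panc-1,SF4,0.8605,0.2584
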