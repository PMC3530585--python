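tree_id,year,lw1_m,pi,pls
1,2005,190,0.4,0.9
1,2006,157,0.11,0.14
2,2005,170,0.24,0.23
2,2006,152,0.36,0.14
3,2005,164,0.56,0.23
3,2006,247,0.63,0.36
4,2005,182,0.39,0.25
4,2006,309,0.49,0.42
5,2005,185,0.32,0.9
5,2006,259,0.49,0.24
6,2005,158,0.49,0.25
6,2006,250,0.56,0.36
7,2005,138,0.5,0.13
7,2006,131,0.14,0.9
8,2005,215,0.28,0.8
8,2006,143,0.36,0.25
9,2005,230,0.64,0.36
9,2006,354,0.66,0.52
10,2005,186,0.65,0.36
10,2006,357,0.77,0.50
11,2005,265,0.48,0.20
11,2006,184,0.54,0.34
12,2005,269,0.15,0.16
12,2006,106,0.21,0.22
13,2005,265,0.65,0.23
13,2006,190,0.68,0.61
14,2005,219,0.61,0.24
14,2006,182,0.73,0.50
15,2005,298,0.26,0.7
15,2006,101,0.38,0.17
16,2005,264,0.34,0.9
16,2006,137,0.46,0.24
17,2005,220,0.39,0.16
17,2006,178,0.49,0.23
18,2005,282,0.19,0.11
18,2006,170,0.34,0.24
19,2005,226,0.54,0.19
19,2006,157,0.56,0.41
20,2005,222,0.10,0.8
20,2006,144,0.25,0.18
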