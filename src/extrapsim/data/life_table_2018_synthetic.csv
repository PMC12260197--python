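# synthetic approximation of a Canadian 2017/19 period life table (both sexes); central death rates, single years of age
age,mx
40,0.000773
41,0.000843
42,0.000920
43,0.001003
44,0.001094
45,0.001193
46,0.001313
47,0.001446
48,0.001591
49,0.001751
50,0.001928
51,0.002121
52,0.002334
53,0.002569
54,0.002827
55,0.003111
56,0.003439
57,0.003801
58,0.004201
59,0.004644
60,0.005134
61,0.005643
62,0.006202
63,0.006817
64,0.007493
65,0.008237
66,0.009102
67,0.010058
68,0.011115
69,0.012283
70,0.013573
71,0.015076
72,0.016744
73,0.018597
74,0.020655
75,0.022940
76,0.025720
77,0.028838
78,0.032333
79,0.036251
80,0.040645
81,0.045912
82,0.051863
83,0.058585
84,0.066177
85,0.074754
86,0.084567
87,0.095669
88,0.108227
89,0.122434
90,0.138507
91,0.153898
92,0.171000
93,0.190002
94,0.211115
95,0.234575
96,0.255174
97,0.277581
98,0.301956
99,0.328471
100,0.357314
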