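# synthetic approximation of a Canadian 1980/82 period life table (both sexes); central death rates, single years of age
age,mx
40,0.001806
41,0.001980
42,0.002170
43,0.002378
44,0.002606
45,0.002857
46,0.003153
47,0.003479
48,0.003840
49,0.004238
50,0.004677
51,0.005140
52,0.005650
53,0.006209
54,0.006825
55,0.007501
56,0.008250
57,0.009073
58,0.009979
59,0.010975
60,0.012070
61,0.013158
62,0.014343
63,0.015635
64,0.017043
65,0.018579
66,0.020318
67,0.022220
68,0.024300
69,0.026575
70,0.029063
71,0.031830
72,0.034861
73,0.038180
74,0.041816
75,0.045798
76,0.050195
77,0.055014
78,0.060297
79,0.066086
80,0.072431
81,0.079295
82,0.086810
83,0.095036
84,0.104043
85,0.113902
86,0.123819
87,0.134599
88,0.146318
89,0.159056
90,0.172904
91,0.185602
92,0.199232
93,0.213864
94,0.229569
95,0.246429
96,0.261253
97,0.276969
98,0.293630
99,0.311294
100,0.330020
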