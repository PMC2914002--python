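angle_deg,k1_star,k2,k3,k4_star,k5,k6
0,0.00000,0.00000,0.000000,0.00000,0.00000,0.00000
10,0.00000,0.00000,0.000000,0.00000,0.00000,0.00000
20,0.00000,0.00000,0.000000,0.00000,0.00000,0.00000
30,0.00150,15.00000,1.000000,0.00000,0.00000,0.00000
40,0.00450,15.00000,1.000000,0.00000,0.00000,0.00000
50,0.00749,15.00000,1.000000,0.00000,0.00000,0.00000
60,0.01049,15.00000,1.000000,0.00000,0.00000,0.00000
70,0.01798,15.00000,1.000000,0.00000,0.00000,0.00000
80,0.04796,15.00000,1.000000,0.00000,0.00000,0.00000
90,0.17290,9.97114,0.006433,1.01566,12.00727,0.07714
100,0.21985,1.67889,0.003459,0.83589,14.95353,0.05500
110,0.20692,0.12304,0.003792,1.08186,2.38274,0.04362
120,0.18484,0.10808,0.003542,0.85176,0.64258,0.03523
130,0.17297,0.21253,0.003417,0.67201,0.25399,0.03149
140,0.18214,0.34664,0.003888,0.60689,1.05519,0.03347
150,0.15555,0.00000,0.003452,0.56272,0.00000,0.03094
160,0.15754,0.00000,0.003679,0.50882,0.11021,0.03178
170,0.15570,0.10760,0.003731,0.45450,1.95509,0.03241
180,0.14206,0.94140,0.003408,0.47168,0.00000,0.02969
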