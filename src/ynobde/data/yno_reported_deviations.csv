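mol_id,expt_bde,dev_b3lyp,dev_f_grnn,dev_g_grnn,dev_gp_grnn
1,43.80,17.17,1.35,-0.08,0.01
2,36.10,7.88,-0.47,0.28,-0.30
3,38.30,9.31,0.76,-0.29,0.29
4,37.60,9.29,0.26,0.01,0.02
5,39.20,9.77,0.04,0.00,0.01
6,34.50,9.13,0.66,-0.61,0.10
7,35.00,9.01,-0.11,0.01,-0.01
8,36.20,12.53,0.15,-0.03,0.01
9,40.40,13.13,0.01,0.00,0.00
10,36.20,10.90,0.05,0.00,0.01
11,21.40,-2.16,-0.22,0.08,-0.06
12,21.40,-2.70,-0.73,0.53,-0.56
13,22.60,-1.72,0.18,-0.29,0.33
14,24.10,0.39,0.07,-0.05,0.06
15,24.30,1.56,-0.01,0.00,0.00
16,21.00,-1.69,-0.02,0.00,-0.01
17,22.30,-2.00,0.04,-0.33,0.30
18,28.30,8.37,1.01,-0.05,0.01
19,28.70,7.30,0.58,-0.11,0.05
20,29.10,6.93,0.29,-0.03,0.67
21,29.20,7.68,-0.24,-0.13,-0.20
22,33.10,10.58,0.01,0.00,-0.01
23,27.50,2.11,0.18,-0.29,0.50
24,23.10,-3.45,-1.43,0.61,-0.59
25,30.30,8.07,0.65,-0.87,0.49
26,29.40,7.90,-0.16,-0.22,-0.10
27,30.50,8.60,0.56,-0.42,0.13
28,26.60,8.22,-0.15,-0.02,0.07
29,25.40,4.97,-0.01,0.00,-0.01
30,33.70,-1.87,-0.01,0.00,0.00
31,33.40,-1.97,0.05,-0.16,0.11
32,34.90,-0.33,0.08,0.00,0.00
33,33.00,-1.91,-0.05,0.16,-0.11
34,33.90,-0.74,0.00,0.00,0.00
35,33.00,-1.92,-0.27,0.27,-0.25
36,33.70,-0.62,0.23,-0.27,0.25
37,28.70,-1.16,-0.03,0.00,0.01
38,28.60,-0.76,-0.42,0.10,-0.02
39,29.00,-0.29,-0.18,-0.03,0.02
40,29.80,0.36,0.05,-0.05,0.06
41,29.30,0.41,-0.03,0.00,0.00
42,28.47,0.04,-0.13,0.04,-0.01
43,29.66,0.26,-0.08,0.02,0.03
44,22.90,1.14,-1.45,1.09,-0.87
45,13.60,0.97,-0.06,0.00,0.00
46,19.20,-0.03,-0.10,0.03,-0.01
47,27.40,-0.87,-0.12,0.01,-0.11
48,28.30,1.67,0.00,0.00,0.00
49,29.70,3.41,0.08,0.00,-0.01
50,13.20,-7.47,-0.07,1.82,-0.38
51,12.40,-5.60,-0.01,0.02,-0.10
52,13.10,-7.03,-0.11,0.26,-0.12
53,14.50,-6.33,0.09,-0.23,0.12
54,32.50,2.62,-0.01,-0.26,0.10
55,32.80,2.88,-0.24,0.04,-0.05
56,33.90,3.88,0.25,-0.04,0.05
57,34.30,3.89,0.01,0.00,0.01
58,38.60,7.57,0.00,0.00,0.01
59,35.00,4.88,-1.38,1.01,-0.97
60,37.90,7.33,1.27,-1.03,1.00
61,36.70,6.90,-0.08,0.24,-0.25
62,33.70,-6.39,0.01,0.00,0.00
63,33.70,-4.12,-0.01,0.00,0.00
64,35.00,9.96,0.01,0.02,-0.01
65,36.20,-4.19,0.01,0.00,0.00
66,36.20,-0.55,-0.01,0.00,0.00
67,21.00,3.51,0.89,-0.17,-0.01
68,21.40,2.46,1.12,-0.81,0.87
69,19.40,-0.27,-0.65,0.38,-0.42
70,19.20,-0.05,-0.24,0.66,-0.65
71,18.60,-2.43,-0.36,0.13,-0.01
72,23.40,-0.20,-0.13,0.00,-0.01
73,20.90,0.88,0.46,-0.66,0.64
74,19.30,-7.91,-0.13,0.26,-0.10
75,19.90,0.36,-0.31,0.44,-0.37
76,25.00,-2.96,0.01,0.00,0.01
77,17.20,-1.69,-1.50,0.21,-0.16
78,24.40,-2.77,-0.01,0.05,-0.12
79,24.30,-2.52,-0.46,0.04,-0.05
80,26.20,-0.84,0.12,0.00,0.01
81,26.10,-1.17,0.01,0.00,0.00
82,26.60,-0.68,0.47,-0.09,0.17
83,29.20,2.03,0.33,-0.49,0.44
84,27.40,0.24,-0.33,0.49,-0.45
85,28.80,7.63,0.08,-0.04,-0.01
86,29.20,4.58,0.01,0.00,0.00
87,27.50,7.16,-0.80,0.17,-0.07
88,27.60,8.00,-0.13,0.77,-0.76
89,26.20,3.70,0.01,0.00,0.00
90,30.40,10.85,0.87,-1.02,0.86
91,31.40,8.77,0.29,-0.09,0.01
92,26.30,8.61,-0.01,-0.01,0.01
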