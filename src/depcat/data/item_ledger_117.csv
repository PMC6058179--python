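item_id,symptom_domain,loading_cfa1,loading_cfa2,exclusion_reasons
1,mood,0.71,0.71,
2,mood,0.73,0.75,Q3
3,mood,0.51,0.52,
4,mood,0.58,0.59,Q3
5,mood,0.75,0.76,Q3+S-X2
6,mood,0.59,0.52,Q3
7,mood,0.67,0.59,
8,cognition,0.57,0.59,
9,somatic,0.43,0.44,
10,somatic,0.22,,CFA
11,cognition,0.21,,CFA
12,mood,0.76,,CFA
13,mood,0.67,0.69,
14,cognition,0.66,0.67,
15,mood,0.75,0.76,
16,mood,0.60,0.62,
17,mood,0.78,,CFA
18,cognition,0.66,0.61,
19,mood,0.64,0.66,Q3+DIF
20,mood,0.60,0.62,
21,mood,0.43,0.45,
22,mood,0.80,0.80,
23,cognition,0.63,0.65,
24,mood,0.72,0.74,Q3
25,somatic,0.32,,CFA
26,mood,0.71,0.72,S-X2
27,mood,0.48,0.48,DIF
28,mood,0.67,0.59,
29,mood,0.80,0.81,
30,mood,0.43,0.38,Discrimination
31,mood,0.68,,CFA
32,mood,0.39,0.32,Q3+Discrimination
33,behavior,0.62,0.63,
34,behavior,0.74,0.76,
35,somatic,0.24,,CFA
36,behavior,0.36,0.31,Discrimination
37,somatic,0.53,0.55,
38,somatic,0.65,0.56,Q3
39,behavior,0.69,0.69,
40,cognition,0.74,0.75,
41,cognition,0.67,0.61,
42,somatic,0.34,0.36,Discrimination
43,behavior,0.68,0.70,
44,behavior,0.60,0.62,
45,behavior,0.57,,CFA
46,cognition,0.82,0.82,
47,somatic,0.50,0.52,
48,cognition,0.43,0.39,Discrimination
49,cognition,0.57,0.60,
50,cognition,0.55,0.56,
51,behavior,0.65,0.67,
52,mood,0.71,0.72,
53,behavior,0.72,0.74,Q3
54,cognition,0.59,0.61,
55,cognition,0.66,0.68,
56,cognition,0.72,0.73,
57,mood,0.71,,CFA
58,cognition,0.59,0.61,
59,cognition,0.60,0.54,
60,cognition,0.54,,CFA
61,cognition,0.81,0.82,
62,cognition,0.33,0.37,S-X2+Discrimination
63,mood,0.77,,CFA
64,somatic,0.47,0.50,
65,behavior,0.47,,CFA
66,cognition,0.61,0.63,
67,cognition,0.58,0.59,Q3
68,cognition,0.73,0.74,
69,cognition,0.78,0.79,
70,behavior,0.60,0.61,
71,behavior,0.76,0.77,
72,cognition,0.77,0.78,
73,cognition,0.75,0.76,
74,cognition,0.79,0.79,
75,cognition,0.72,0.73,
76,cognition,0.67,,CFA
77,mood,0.76,0.78,
78,cognition,0.67,0.69,
79,cognition,0.71,,CFA
80,cognition,0.76,0.77,
81,cognition,0.64,0.65,
82,mood,0.63,0.64,
83,cognition,0.83,0.83,S-X2
84,cognition,0.82,0.82,
85,cognition,0.41,,CFA
86,cognition,0.82,0.82,
87,cognition,-0.40,,CFA
88,suicide,0.84,0.84,Q3
89,suicide,0.78,0.79,
90,cognition,0.61,0.63,
91,suicide,0.85,0.84,Q3
92,suicide,0.87,0.87,Q3
93,mood,0.49,0.51,DIF
94,cognition,0.61,,CFA
95,suicide,0.78,,CFA
96,somatic,0.68,,CFA
97,somatic,0.41,0.41,Q3+Discrimination
98,somatic,0.48,,CFA
99,mood,0.80,0.80,
100,somatic,0.48,0.49,
101,somatic,0.12,,CFA
102,cognition,0.76,0.78,Q3
103,behavior,0.59,0.61,
104,behavior,0.79,0.80,
105,cognition,0.73,0.75,
106,suicide,0.78,0.78,
107,mood,0.72,0.73,
108,behavior,0.29,0.32,Discrimination
109,suicide,0.85,0.86,
110,cognition,0.88,0.88,
111,behavior,0.82,0.83,
112,mood,0.52,,CFA
113,cognition,0.65,0.67,
114,behavior,0.71,0.72,
115,behavior,0.78,0.79,
116,mood,0.74,,CFA
117,suicide,0.69,0.68,S-X2
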