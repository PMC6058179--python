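item_id,model,n_categories,a,b1,b2,b3,symptom_domain,content
1,GRM,4,1.68,-0.67,1.40,2.49,mood,Pessimism
2,GRM,4,1.03,-1.13,0.84,2.27,mood,Happy as others
3,GRM,4,1.24,-1.57,0.47,2.38,mood,Happiness
4,GRM,4,1.30,-0.15,2.24,4.12,cognition,Being reproached
5,GRM,4,0.84,0.13,3.17,5.39,somatic,Loss of appetite
6,GRM,4,1.62,-0.99,1.97,2.97,mood,Loss of interest
7,GRM,4,1.69,-0.06,1.91,3.27,cognition,Being despised
8,GRM,4,2.05,0.02,1.45,2.45,mood,Still depressed with others' help
9,GRM,4,1.39,-1.17,1.48,3.16,mood,Agitation
10,GRM,4,1.29,-1.13,0.66,2.34,cognition,Good as others
11,GRM,4,1.40,-1.16,1.00,2.67,mood,Boring
12,GRM,4,0.88,-0.37,2.06,3.63,mood,Social withdrawal
13,GRM,4,2.32,0.36,1.62,2.50,mood,Loss of pleasure
14,GRM,4,1.51,-0.74,1.30,2.73,cognition,Concentration difficulty
15,GRM,4,1.27,-1.76,0.02,1.99,mood,Interested in everything around
16,GRM,4,2.49,-0.57,1.17,2.24,mood,Gloomy mood
17,GRM,4,1.47,-0.51,1.75,3.00,behavior,So tired and unable to do anything
18,GRM,4,2.04,-0.31,1.39,2.52,behavior,Everything is laborious
19,GRM,4,1.12,-1.26,2.04,3.33,somatic,Sleep disorders
20,GRM,4,1.70,1.11,2.23,3.30,behavior,Feel like body had rotted away
21,GRM,4,2.05,0.02,1.65,2.73,cognition,Difficulties around
22,GRM,4,1.34,-1.11,0.52,2.18,cognition,Future is promising
23,GRM,4,1.65,-0.47,1.49,2.67,behavior,Hypodynamia
24,GRM,4,1.48,-0.78,1.39,2.78,behavior,Difficult to start
25,GRM,4,2.62,0.00,1.31,2.12,cognition,Sense of failure
26,GRM,4,1.09,0.17,2.86,4.46,somatic,Rapid heart beat
27,GRM,4,1.34,-1.14,1.06,2.48,cognition,Immersion in the past
28,GRM,4,1.22,-1.20,1.13,2.98,cognition,Draw a blank
29,GRM,4,1.62,-1.30,1.78,3.09,behavior,Tiredness or fatigue
30,GRM,4,1.99,-0.35,1.54,2.80,mood,Fear
31,GRM,4,1.39,-1.02,1.10,2.70,cognition,Indecisiveness
32,GRM,4,1.64,-0.61,1.41,2.75,cognition,Reasoning difficulty
33,GRM,4,1.97,-0.17,1.54,2.60,cognition,Mind blank
34,GRM,4,1.44,-1.04,1.15,2.66,cognition,Irresolution
35,GRM,4,1.25,-1.33,0.60,2.37,cognition,Clear mind
36,GRM,4,2.64,-0.29,1.23,2.12,cognition,Disappointment
37,GRM,4,1.03,-1.54,2.41,3.96,somatic,Poor appetite or eating too much
38,GRM,4,1.50,-0.83,1.33,2.63,cognition,Unattractiveness feelings
39,GRM,4,1.99,-0.46,1.26,2.49,cognition,Worse than others
40,GRM,4,2.40,-0.10,1.38,2.38,cognition,Self-assessment low
41,GRM,4,1.45,-0.63,1.33,2.68,behavior,Talk less
42,GRM,4,2.27,-0.32,1.23,2.31,behavior,Uncalm
43,GRM,4,2.29,-0.27,1.26,2.29,cognition,Cognitive symptom (reconstructed)
44,GRM,4,2.18,-0.21,1.29,2.26,cognition,Not needed feelings
45,GRM,4,2.29,0.40,1.65,2.53,cognition,Self-dislike
46,GRM,4,1.99,-0.48,1.12,2.03,cognition,Loneliness
47,GRM,4,2.05,0.28,1.75,2.74,mood,Feel like crying
48,GRM,4,1.66,-0.75,2.13,2.96,cognition,Self-criticalness
49,GRM,4,2.25,-0.16,1.39,2.22,cognition,Helplessness
50,GRM,4,1.55,0.19,2.34,3.60,cognition,Unfriendly treatment feelings
51,GRM,4,1.50,-0.31,1.73,3.18,mood,Irritability
52,GRM,4,2.56,0.41,1.60,2.44,cognition,Future is not appealing
53,GRM,4,2.59,0.27,1.55,2.45,cognition,Have no future
54,GRM,4,1.87,0.68,1.89,2.73,suicide,Suicidal thoughts
55,GRM,4,1.41,-1.01,2.21,3.49,cognition,Concentration or memory difficulty
56,GRM,4,2.40,-0.64,1.15,2.03,mood,Sadness
57,GRM,4,0.99,0.09,2.66,4.29,somatic,Eating too much or little
58,GRM,4,1.31,-0.69,2.60,3.74,behavior,Dilatory or intense behavior
59,GRM,4,2.31,-0.25,1.33,2.31,behavior,Restlessness
60,GRM,4,2.10,0.12,1.73,2.79,cognition,Unpopularity
61,GRM,4,1.96,1.01,2.14,3.01,suicide,Others' life will be better without me
62,GRM,4,1.87,-0.13,1.21,2.22,mood,Smile less
63,GRM,4,2.94,0.26,1.58,2.23,suicide,No good things
64,GRM,4,3.14,0.41,1.48,2.45,cognition,Despair
65,GRM,4,2.61,0.41,1.61,2.32,behavior,Unable to continue daily work
66,GRM,4,1.71,-1.16,1.19,2.41,cognition,Regret and upset
67,GRM,4,1.81,0.38,2.07,3.08,behavior,Unable to provide for oneself
68,GRM,4,2.27,0.42,1.65,2.39,behavior,Unable to restart
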