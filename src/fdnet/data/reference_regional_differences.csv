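roi_index,abbreviation,hemisphere,middle_mean,elderly_mean,p_value
1,CACg,left,2.1081,2.0668,0.037
15,Tr,left,2.2499,2.2334,0.044
21,RoMF,left,2.4128,2.3997,0.005
22,RoMF,right,2.4128,2.4014,0.048
37,MT,left,2.3118,2.2989,0.043
38,MT,right,2.3254,2.3103,0.018
41,ST,left,2.3267,2.3148,0.033
42,ST,right,2.3392,2.329,0.037
39,PaH,left,2.0762,2.0536,0.035
36,IT,right,2.3278,2.3138,0.031
53,PoCg,left,2.1961,2.1684,0.038
55,PreCu,left,2.3302,2.3171,0.045
57,SP,left,2.3567,2.3487,0.031
58,SP,right,2.3567,2.3487,0.016
67,PerCa,left,2.0416,2.0935,0.0009
68,PerCa,right,2.0836,2.1097,0.04
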