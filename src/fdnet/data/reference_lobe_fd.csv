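lobe,hemisphere,middle_mean,middle_sd,elderly_mean,elderly_sd,p_value
frontal,both,2.2399,0.1035,2.2326,0.1032,0.0221
frontal,left,2.2375,0.1091,2.2294,0.1109,0.0336
frontal,right,2.2423,0.1017,2.2358,0.0989,0.0374
temporal,both,2.1991,0.1232,2.1897,0.1244,0.0084
temporal,left,2.2065,0.1145,2.1968,0.1171,0.003
temporal,right,2.1918,0.1379,2.1825,0.138,0.034
parietal,both,2.2972,0.1047,2.2858,0.1078,0.0005
parietal,left,2.2953,0.1055,2.2833,0.1109,0.0026
parietal,right,2.2990,0.1122,2.2882,0.1135,0.00025
occipital,both,2.2033,0.1306,2.2134,0.1139,0.0267
occipital,left,2.1908,0.151,2.2061,0.1283,0.007
occipital,right,2.2159,0.1287,2.2208,0.1170,0.348
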