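index,name,abbreviation,hemisphere,lobe
1,Caudal anterior cingulate,CACg,left,frontal
2,Caudal anterior cingulate,CACg,right,frontal
3,Caudal middle frontal,CMF,left,frontal
4,Caudal middle frontal,CMF,right,frontal
5,Lateral orbito frontal,LOrF,left,frontal
6,Lateral orbito frontal,LOrF,right,frontal
7,Medial orbito frontal,MOrF,left,frontal
8,Medial orbito frontal,MOrF,right,frontal
9,Paracentral,PaC,left,frontal
10,Paracentral,PaC,right,frontal
11,Parsopercularis,Op,left,frontal
12,Parsopercularis,Op,right,frontal
13,Parsorbitalis,Or,left,frontal
14,Parsorbitalis,Or,right,frontal
15,Parstriangularis,Tr,left,frontal
16,Parstriangularis,Tr,right,frontal
17,Precentral,PreC,left,frontal
18,Precentral,PreC,right,frontal
19,Rostral anterior cingulate,RoACg,left,frontal
20,Rostral anterior cingulate,RoACg,right,frontal
21,Rostral middle frontal,RoMF,left,frontal
22,Rostral middle frontal,RoMF,right,frontal
23,Superior frontal,SF,left,frontal
24,Superior frontal,SF,right,frontal
25,Frontalpole,FPol,left,frontal
26,Frontalpole,FPol,right,frontal
27,Insula,Ins,left,frontal
28,Insula,Ins,right,frontal
29,Bankssts,B,left,temporal
30,Bankssts,B,right,temporal
31,Entorhinal,En,left,temporal
32,Entorhinal,En,right,temporal
33,Fusiform,Fu,left,temporal
34,Fusiform,Fu,right,temporal
35,Inferior temporal,IT,left,temporal
36,Inferior temporal,IT,right,temporal
37,Middle temporal,MT,left,temporal
38,Middle temporal,MT,right,temporal
39,Parahippocampal,PaH,left,temporal
40,Parahippocampal,PaH,right,temporal
41,Superior temporal,ST,left,temporal
42,Superior temporal,ST,right,temporal
43,Temporal pole,TPol,left,temporal
44,Temporal pole,TPol,right,temporal
45,Transverse temporal,TrT,left,temporal
46,Transverse temporal,TrT,right,temporal
47,Inferior parietal,IP,left,parietal
48,Inferior parietal,IP,right,parietal
49,Isthmus cingulate,IstCg,left,parietal
50,Isthmus cingulate,IstCg,right,parietal
51,Postcentral,PoC,left,parietal
52,Postcentral,PoC,right,parietal
53,Posterior cingulate,PoCg,left,parietal
54,Posterior cingulate,PoCg,right,parietal
55,Precuneus,PreCu,left,parietal
56,Precuneus,PreCu,right,parietal
57,Superior parietal,SP,left,parietal
58,Superior parietal,SP,right,parietal
59,Supra marginal,SM,left,parietal
60,Supra marginal,SM,right,parietal
61,Cuneus,Cu,left,occipital
62,Cuneus,Cu,right,occipital
63,Lateral occipital,LO,left,occipital
64,Lateral occipital,LO,right,occipital
65,Lingual,Lg,left,occipital
66,Lingual,Lg,right,occipital
67,Pericalcarine,PerCa,left,occipital
68,Pericalcarine,PerCa,right,occipital
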