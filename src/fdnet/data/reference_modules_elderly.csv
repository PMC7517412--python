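roi_index,module
13,1
19,1
20,1
21,1
27,1
4,1
6,1
10,1
43,1
38,1
42,1
51,1
55,1
57,1
50,1
56,1
63,1
64,1
66,1
3,2
17,2
18,2
2,2
12,2
16,2
33,2
39,2
32,2
34,2
40,2
46,2
49,2
53,2
54,2
60,2
67,2
1,3
5,3
7,3
9,3
11,3
15,3
23,3
22,3
28,3
29,3
37,3
41,3
59,3
52,3
61,3
65,3
68,3
8,4
14,4
24,4
26,4
31,4
30,4
47,4
62,4
25,5
35,5
36,5
45,5
44,5
58,5
48,5
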