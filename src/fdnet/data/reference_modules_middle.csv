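roi_index,module
1,1
2,1
3,1
4,1
5,1
9,1
13,1
15,1
16,1
17,1
18,1
20,1
26,1
27,1
37,1
30,1
44,1
47,1
54,1
58,1
65,1
67,1
7,2
23,2
14,2
33,2
32,2
38,2
46,2
51,2
59,2
49,2
52,2
63,2
64,2
62,2
19,3
25,3
10,3
12,3
24,3
31,3
43,3
45,3
40,3
42,3
53,3
50,3
60,3
11,4
21,4
22,4
6,4
35,4
39,4
41,4
34,4
36,4
55,4
61,4
8,5
28,5
29,5
57,5
48,5
56,5
66,5
68,5
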