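# fixed 31x5 study Q-matrix: all nonempty attribute subsets, ordered by (row sum, lexicographic)
item_id,attr1,attr2,attr3,attr4,attr5
1,1,0,0,0,0
2,0,1,0,0,0
3,0,0,1,0,0
4,0,0,0,1,0
5,0,0,0,0,1
6,1,1,0,0,0
7,1,0,1,0,0
8,1,0,0,1,0
9,1,0,0,0,1
10,0,1,1,0,0
11,0,1,0,1,0
12,0,1,0,0,1
13,0,0,1,1,0
14,0,0,1,0,1
15,0,0,0,1,1
16,1,1,1,0,0
17,1,1,0,1,0
18,1,1,0,0,1
19,1,0,1,1,0
20,1,0,1,0,1
21,1,0,0,1,1
22,0,1,1,1,0
23,0,1,1,0,1
24,0,1,0,1,1
25,0,0,1,1,1
26,1,1,1,1,0
27,1,1,1,0,1
28,1,1,0,1,1
29,1,0,1,1,1
30,0,1,1,1,1
31,1,1,1,1,1
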