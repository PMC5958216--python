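# frozen baseline slipping/guessing draw, U[0.1,0.3], seed=5101
item_id,slipping,guessing
1,0.1531236490,0.1820396110
2,0.2955364800,0.2424694901
3,0.2098505328,0.2090005821
4,0.2627739558,0.1361023704
5,0.1918357485,0.1190862197
6,0.2139150701,0.1734937220
7,0.2928577679,0.1207853622
8,0.1849899324,0.1008820278
9,0.1494253193,0.1995344787
10,0.2962020808,0.2392019626
11,0.2424714587,0.1948027800
12,0.2919488834,0.1323739228
13,0.2443693215,0.2889599144
14,0.2963172779,0.2665552496
15,0.1616582541,0.2041951201
16,0.1107530837,0.1330551403
17,0.2266857459,0.2304416995
18,0.1661710326,0.1006229318
19,0.2143958089,0.1911345745
20,0.1984650901,0.2282185884
21,0.2782694654,0.2309256299
22,0.1842684407,0.2745283400
23,0.2438382742,0.2959923081
24,0.1366572542,0.1032513682
25,0.2697671437,0.1121373427
26,0.2740431844,0.2449584717
27,0.2838463682,0.1154343237
28,0.1297084080,0.1082848912
29,0.2549770594,0.2642637690
30,0.2705642080,0.1198151365
31,0.2698934157,0.1455953148
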