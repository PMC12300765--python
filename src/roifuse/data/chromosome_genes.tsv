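chromosome	gene_count	copy_number
1	3000	2
2	2500	2
3	1900	2
4	1600	2
5	1700	2
6	1900	2
7	1800	2
8	1400	2
9	1400	2
10	1400	2
11	2000	2
12	1600	2
13	800	2
14	1200	2
15	1200	2
16	1300	2
17	1600	2
18	600	2
19	1700	2
20	900	2
21	400	2
22	800	2
X	1400	1
Y	200	1
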