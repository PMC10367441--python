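node_i	node_j	weight
2	23	1
2	37	1
3	7	1
3	8	1
3	20	1
3	30	1
4	34	1
5	9	1
5	24	1
5	35	1
6	32	1
7	39	1
8	14	1
8	25	1
8	28	1
8	39	1
9	10	1
10	33	1
11	18	1
12	28	1
14	27	1
14	32	1
15	21	1
15	36	1
17	37	1
18	24	1
18	31	1
19	21	1
19	29	1
19	31	1
19	40	1
20	38	1
22	33	1
23	38	1
24	28	1
24	37	1
27	38	1
28	38	1
28	39	1
29	35	1
29	38	1
30	35	1
32	33	1
33	36	1
33	37	1
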