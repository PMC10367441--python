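node_i	node_j	weight
1	25	1
3	10	1
3	14	1
3	26	1
4	27	1
4	33	1
4	37	1
5	16	1
5	21	1
6	8	1
6	9	1
6	24	1
6	37	1
6	40	1
7	26	1
7	40	1
8	12	1
8	20	1
8	30	1
9	28	1
10	31	1
11	26	1
11	27	1
11	28	1
11	38	1
12	17	1
13	18	1
13	22	1
13	37	1
14	17	1
15	17	1
15	34	1
16	23	1
16	27	1
16	35	1
16	38	1
16	40	1
17	32	1
17	38	1
18	19	1
18	20	1
18	28	1
19	20	1
19	27	1
19	36	1
21	28	1
21	32	1
21	39	1
21	40	1
22	29	1
22	36	1
22	38	1
23	33	1
23	39	1
24	30	1
27	29	1
27	32	1
34	38	1
37	38	1
38	39	1
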