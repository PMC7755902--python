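feature	gene_a	gene_b	relation	active
1	CD28	CD86	greater	1
2	CD27	PDCD1	greater	1
3	CD40	CD28	greater	1
4	CD40	CD80	greater	1
5	CD40	CD274	greater	1
6	CD40	PDCD1	greater	1
7	CD86	TNFSF4	greater	1
8	CD86	CD200	greater	1
9	CTLA4	TNFSF4	greater	1
10	PDCD1	TNFSF4	greater	1
11	CD80	TNFSF9	greater	1
12	CD28	CD276	greater	1
13	CD27	TNFRSF14	less	1
14	HLA-DRA	CD40LG	greater	1
15	TIGIT	LAG3	less	0
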