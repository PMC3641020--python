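k	CALM1	HIF1A	IFNG	KNG1	NOS3	NPY	REN	accuracy	n_networks
1	0	0	0	0	69	0	0	0.86795	69
2	0	0	0	0	68	0	0	0.86849	68
3	0	1	0	13	14	1	1	0.78395	30
4	0	0	0	10	15	3	2	0.77901	30
5	0	1	0	12	16	0	1	0.77778	30
6	3	1	0	8	15	1	2	0.77654	30
7	2	1	1	7	14	1	4	0.77037	30
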