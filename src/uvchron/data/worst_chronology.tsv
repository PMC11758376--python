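1	TTT	AAA
2	GAA	TTC
3	CTT	AAG
4	TTA	TAA
5	ATT	AAT
6	TCT	AGA
7	CAA	TTG
8	GTT	AAC
9	GGA	TCC
10	CCT	AGG
11	ACT	AGT
12	TCA	TGA
13	GAG	CTC
14	GAT	ATC
15	CTA	TAG
16	GCT	AGC
17	TCG	CGA
18	GGG	CCC
19	CCA	TGG
20	ATA	TAT
21	GAC	GTC
22	ACA	TGT
23	GGT	ACC
24	CTG	CAG
25	ATG	CAT
26	GTA	TAC
27	GTG	CAC
28	CCG	CGG
29	GGC	GCC
30	ACG	CGT
31	GCG	CGC
32	GCA	TGC
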