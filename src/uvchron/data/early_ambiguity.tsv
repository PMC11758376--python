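1	GCG/CGC|GCA/TGC|ACG/CGT|ACA/TGT
2	GCG/CGC|GCA/TGC|ACG/CGT|ACA/TGT
3	GCG/CGC|GCA/TGC|ACG/CGT|ACA/TGT
4	GCG/CGC|GCA/TGC|ACG/CGT|ACA/TGT
5	GTG/CAC
6	GGC/GCC
7	CCG/CGG
8	ATG/CAT
9	GGT/ACC
10	GAC/GTC
11	GTA/TAC
12	GCT/AGC
13	CCA/TGG
14	CTG/CAG
15	TCG/CGA
16	ATA/TAT
17	GGG/CCC
18	CTA/TAG
19	ACT/AGT
20	TCA/TGA
21	GAT/ATC
22	CAA/TTG
23	GAG/CTC
24	GGA/TCC
25	CCT/AGG
26	GTT/AAC
27	TCT/AGA
28	TTA/TAA
29	ATT/AAT
30	CTT/AAG
31	GAA/TTC
32	TTT/AAA
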