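number	sample	chrom	pos	change	kind
1	I-D6	LG1	12190579	G->A	SNM
2	I-D9	LG2	6364117	G->A	SNM
3	I-D12	LG2	3927622	C->T	SNM
4	I-D20	LG3	1376136	G->A	SNM
5	I-D15	LG3	5786680	T->C	SNM
6	I-D22	LG3	14425758	G->A	SNM
7	I-D1	LG6	10066783	C->T	SNM
8	I-D18	LG8	4772520	C->T	SNM
9	I-D21	LG8	4887207	C->T	SNM
10	I-D4	LG8	1918198	C->T	SNM
11	I-D15	LG9	4539315	G->A	SNM
12	I-D20	LG9	10120753	A->G	SNM
13	I-D1	LG12	6547520	G->A	SNM
14	I-D1	LG12	317275	T->C	SNM
15	I-D13	LG13	4778391	G->A	SNM
16	I-D19	LG13	5813863	G->A	SNM
17	I-D15	LG15	8684993	C->T	SNM
18	II-D21	LG11	10939409	C->T	SNM
19	II-D4	LG5	3035192	C->T	SNM
20	II-D4	LG5	5897739	G->A	SNM
21	II-D16	LG1	7973774	G->A	SNM
22	II-D17	LG1	204068	G->A	SNM
23	II-D16	LG7	12154508	C->T	SNM
24	I-D6	LG1	7408143	GATTCCGATTCGGATTCC_deletion	indel
25	II-D14	LG14	6588726	C_deletion	indel
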