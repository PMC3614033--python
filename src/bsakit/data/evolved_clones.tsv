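# Putative causal mutations in twelve sucrose-evolved yeast clones (reference dataset).
# Nucleotide positions are CDS-relative, base 1 = first coding base; negative = promoter.
# One row per nucleotide change; a gene may appear twice in one clone (e.g. MED1 in EvoClone9).
clone	nominal_generations	total_mutations	gene	nt_name	aa_name	mutant_reads	total_reads
EvoClone1	307	71	ACE2	703 G->T	E235*	77	79
EvoClone1	307	71	IRA1	8987 C->G	T2996S	99	102
EvoClone1	307	71	PHO87	196 G->C	A66P	55	55
EvoClone1	307	71	RGT1	3157 C->T	Q1053*	72	74
EvoClone1	307	71	SAN1	1707 C->A	N569K	76	77
EvoClone1	307	71	SIN4	383 G->A	G128D	106	106
EvoClone1	307	71	UBR1	1916 T->A	L639*	42	44
EvoClone2	273	115	ACE2	968 T->A	L323*	110	110
EvoClone2	273	115	CSE2	100_100delT	S35Rfs54	102	107
EvoClone2	273	115	IRA1	7657 A->T	S2553C	72	75
EvoClone2	273	115	MTH1	459_459delC	H154Tfs156	93	100
EvoClone2	273	115	UBR1	524 G->A	C175Y	104	112
EvoClone3	301	252	IRA2	8081 C->A	S2694Y	75	81
EvoClone3	301	252	IRC8	365 T->C	L122P	84	88
EvoClone3	301	252	NAT1	1782 G->A	W594*	84	87
EvoClone3	301	252	SYP1	1376 C->T	T459I	90	96
EvoClone4	229	95	ACE2	670 G->T	E224*	93	93
EvoClone4	229	95	RGT1	2494_2495insT	L832Ffs834	135	139
EvoClone4	229	95	SIN4	382 G->A	G128S	104	105
EvoClone4	229	95	UBR1	1916 T->A	L639*	56	61
EvoClone5	237	120	ACE2	565 C->T	Q189*	149	152
EvoClone5	237	120	ARO2	371 C->G	A124G	93	101
EvoClone5	237	120	MCK1	38_38delG	G14Dfs22	152	158
EvoClone5	237	120	SNF2	71 G->T	R24I	94	100
EvoClone5	237	120	SNF3	1235 T->A	V412E	148	148
EvoClone6	232	110	ACE2	507_507delT	N169Kfs177	142	146
EvoClone6	232	110	GCN2	892 A->G	N298D	115	117
EvoClone6	232	110	GPB2	235 G->T	E79*	144	145
EvoClone6	232	110	MTH1	152_152delG	S51Ifs56	110	112
EvoClone6	232	110	NRG1	371 C->A	S124*	92	95
EvoClone6	232	110	RAD6	191 C->A	P64H	127	135
EvoClone7A	242	105	ACE2	1901 C->A	S634*	84	87
EvoClone7A	242	105	RAD61	225 T->A	N75K	97	97
EvoClone7B	242	94	GCN3	176 C->A	S59Y	79	87
EvoClone7B	242	94	IRA2	7049_7049delC	A2350Gfs2354	129	132
EvoClone7B	242	94	RAM1	566 T->A	L189Q	133	137
EvoClone7B	242	94	SAN1	1464 C->G	N488K	97	100
EvoClone7B	242	94	SNF3	692 C->A	A231D	87	90
EvoClone7C	242	115	GCR2	533 T->A	L178Q	148	154
EvoClone7C	242	115	IRA2	7049_7049delC	A2350Gfs2354	166	169
EvoClone7C	242	115	PDR1	2527 G->A	D843N	145	159
EvoClone7C	242	115	PUF4	1960 C->T	Q654*	184	202
EvoClone8	253	122	ACE2	-379 G->A	Promoter	103	103
EvoClone8	253	122	AXL2	700 T->C	S234P	87	87
EvoClone8	253	122	ERG1	427 G->A	E143K	160	163
EvoClone8	253	122	HXK1	93 A->T	E31D	200	217
EvoClone8	253	122	IFM1	1724 T->A	I575N	130	134
EvoClone8	253	122	MIT1	188 G->A	W63*	131	142
EvoClone8	253	122	SKS1	1311 C->G	Y437*	152	152
EvoClone8	253	122	SNF3	1237 G->A	E413K	101	101
EvoClone8	253	122	UBC5	443 A->G	D118G	137	141
EvoClone8	253	122	UBR1	3859_3859delG	G1287Dfs1345	170	179
EvoClone9	265	126	ARE1	-10 G->T	Promoter	127	127
EvoClone9	265	126	GCN2	4582 A->C	I1528L	125	137
EvoClone9	265	126	GIN4	57 G->A	W19*	79	81
EvoClone9	265	126	IRC8	170 G->T	G57V	118	119
EvoClone9	265	126	MCD1	524 C->T	S175L	115	115
EvoClone9	265	126	MCK1	675_675delG	G227Vfs249	114	116
EvoClone9	265	126	MED1	1009 C->G	L337V	104	113
EvoClone9	265	126	MED1	1465 G->T	E489*	118	125
EvoClone9	265	126	UBR1	3148_3148delC	L1050Yfs1063	141	145
EvoClone10	242	196	ACE2	1874 A->T	Q625L	121	122
EvoClone10	242	196	AXL2	432_432delC	Y145Mfs154	161	164
EvoClone10	242	196	BPH1	2369 C->A	S790Y	144	144
EvoClone10	242	196	DNF2	2351 T->C	F784S	90	97
EvoClone10	242	196	ECM5	3466 G->A	D1156N	127	128
EvoClone10	242	196	ENP2	1129 T->A	F377I	127	132
EvoClone10	242	196	GAC1	-7 T->A	Promoter	106	117
EvoClone10	242	196	HTZ1	-369 T->C	Promoter	69	73
EvoClone10	242	196	KEM1	2268 G->A	M756I	148	148
EvoClone10	242	196	MCD1	-28 G->T	Promoter	153	153
EvoClone10	242	196	MPT5	2409 T->A	L590*	146	146
EvoClone10	242	196	MRPS17	325 G->A	D109N	141	147
EvoClone10	242	196	NUT1	2582 C->A	S861*	166	169
EvoClone10	242	196	PRC1	-283 G->A	Promoter	138	148
EvoClone10	242	196	RGT1	2060 G->T	G687V	91	91
EvoClone10	242	196	SAC6	1736 A->T	K542M	125	137
EvoClone10	242	196	TOP3	1679 T->C	V560A	100	103
EvoClone10	242	196	UBR1	56 T->A	L19Q	130	140
EvoClone10	242	196	WHI2	187 G->T	E63*	138	139
EvoClone10	242	196	WTM2	-297 T->A	Promoter	125	129
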